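"""Per-peptide two-group testing, signature selection and plug-in FDR.

Each peptide is tested independently with a two-tailed two-sample t-test
(pooled-variance Student by default, Welch optionally); peptides with raw
``p < alpha`` form the discriminating signature.  No multiplicity
adjustment is applied to the selection itself — with m peptides tested at
level alpha, the expected false-discovery burden is instead summarized post
hoc by the plug-in estimate ``m·alpha / k`` for k discoveries (or its
``(m−k)·alpha / k`` variant that treats only the non-discoveries as null).
Benjamini–Hochberg adjusted p-values are available separately for users who
want a formal FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import NoDiscoveriesError
from .preprocess import InhibitionProfile, SignalMatrix

DEFAULT_ALPHA = 0.05


@dataclass
class PeptideTestResult:
    """Outcome of one per-peptide two-group comparison."""

    peptide_id: str
    group_means: tuple[float, float]
    mean_difference: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    significant: bool
    degenerate: bool = False  # zero variance in both groups, equal means


@dataclass
class SignatureSet:
    """Peptides called significant for one contrast, in panel order."""

    peptide_ids: tuple[str, ...]
    alpha: float
    source: str = ""
    _members: frozenset = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._members = frozenset(self.peptide_ids)

    def __contains__(self, peptide_id: str) -> bool:
        return peptide_id in self._members

    def __len__(self) -> int:
        return len(self.peptide_ids)


def two_sample_t(a, b, variant: str = "pooled") -> PeptideTestResult:
    """Two-tailed two-sample t-test on two value vectors.

    ``pooled`` uses the pooled-variance Student statistic with
    ``df = n_a + n_b − 2``; ``welch`` uses Satterthwaite degrees of freedom.
    The sign convention is ``t ∝ mean(a) − mean(b)``.

    A fully degenerate input (zero variance in both groups, equal means)
    yields ``t = 0, p = 1`` with the ``degenerate`` flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")

    mean_a, mean_b = float(a.mean()), float(b.mean())
    if a.var() == 0.0 and b.var() == 0.0:
        degenerate = True
        if mean_a == mean_b:
            t, p, df = 0.0, 1.0, float(len(a) + len(b) - 2)
        else:
            t = np.inf if mean_a > mean_b else -np.inf
            p, df = 0.0, float(len(a) + len(b) - 2)
    else:
        degenerate = False
        res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
        t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    return PeptideTestResult(
        peptide_id="",
        group_means=(mean_a, mean_b),
        mean_difference=mean_a - mean_b,
        t_statistic=t,
        degrees_of_freedom=df,
        p_value=p,
        significant=p < DEFAULT_ALPHA,
        degenerate=degenerate,
    )


def test_all_peptides(
    mat: SignalMatrix | InhibitionProfile | pd.DataFrame,
    groups: dict[str, list[str]] | tuple[list[str], list[str]],
    alpha: float = DEFAULT_ALPHA,
    variant: str = "pooled",
) -> list[PeptideTestResult]:
    """Run the per-peptide t-test over every column of a samples × peptides matrix.

    ``groups`` gives the two sample partitions, either as a mapping of two
    group names to sample-id lists or as a pair of lists; the first group
    plays the role of ``a`` in :func:`two_sample_t`.  Individual p-values
    are reported raw (no multiplicity adjustment).  Peptide order follows
    the matrix columns.
    """
    df = _values(mat)
    if isinstance(groups, dict):
        if len(groups) != 2:
            raise ValueError("exactly two groups required")
        (ga, gb) = groups.values()
    else:
        ga, gb = groups
    missing = (set(ga) | set(gb)) - set(df.index)
    if missing:
        raise ValueError(f"samples not in matrix: {sorted(missing)}")
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each group needs at least 2 samples")

    A = df.loc[list(ga)].to_numpy()
    B = df.loc[list(gb)].to_numpy()
    results = []
    for j, pep in enumerate(df.columns):
        r = two_sample_t(A[:, j], B[:, j], variant=variant)
        r.peptide_id = pep
        r.significant = r.p_value < alpha
        results.append(r)
    return results


test_all_peptides.__test__ = False  # keep pytest from collecting the API name


def results_frame(results: list[PeptideTestResult]) -> pd.DataFrame:
    """Tabulate test results (one row per peptide, panel order preserved)."""
    return pd.DataFrame(
        {
            "peptide_id": [r.peptide_id for r in results],
            "mean_a": [r.group_means[0] for r in results],
            "mean_b": [r.group_means[1] for r in results],
            "mean_diff": [r.mean_difference for r in results],
            "t": [r.t_statistic for r in results],
            "df": [r.degrees_of_freedom for r in results],
            "p": [r.p_value for r in results],
            "significant": [r.significant for r in results],
        }
    )


def select_signature(
    results: list[PeptideTestResult], alpha: float = DEFAULT_ALPHA, source: str = ""
) -> SignatureSet:
    """Peptides with raw p < alpha, in input (panel) order."""
    chosen = tuple(r.peptide_id for r in results if r.p_value < alpha)
    return SignatureSet(chosen, alpha=alpha, source=source)


def plug_in_fdr(
    m: int, k: int, alpha: float, null_fraction: str = "all_m"
) -> float:
    """Plug-in false-discovery-rate estimate for k of m features at level alpha.

    ``all_m`` assumes all m features null (E[false positives] = m·alpha);
    ``m_minus_k`` counts only the m−k non-discoveries as null.  Returned as
    a fraction (0.18, not 18%).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if k < 1:
        raise NoDiscoveriesError("no discoveries: plug-in FDR undefined")
    if m < k:
        raise ValueError("m must be at least k")
    if null_fraction == "all_m":
        return m * alpha / k
    if null_fraction == "m_minus_k":
        return (m - k) * alpha / k
    raise ValueError(f"unknown null_fraction {null_fraction!r}")


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (optional extra; not used for selection)."""
    return stats.false_discovery_control(np.asarray(p_values, dtype=float))


def _values(mat) -> pd.DataFrame:
    if isinstance(mat, SignalMatrix):
        return mat.values
    if isinstance(mat, InhibitionProfile):
        return mat.lfc
    if isinstance(mat, pd.DataFrame):
        return mat
    raise TypeError(f"unsupported matrix type {type(mat)!r}")
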