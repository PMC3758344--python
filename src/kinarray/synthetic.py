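"""Synthetic paired kinase-array experiments with known ground truth.

The generator emulates the statistical structure of the melanoma study so
every pipeline stage can be exercised without the deposited raw arrays:

* 144 substrate peptides, three technical replicates, two experimental
  series, paired with/without-inhibitor arrays on the same chip;
* tumor-vs-normal signal elevation of up to ~5-fold (log2 effect drawn
  uniformly in [0, log2 5]) for a majority (default 85%) of peptides; the
  remainder are mildly *depressed* in tumor (a small negative effect), so
  the observed fraction of tumor-elevated peptides emulates the 80–90%
  reported for real arrays rather than drifting toward ~92% as exact-zero
  effects would under tie-breaking noise;
* a median inhibition of roughly 50% (base log2 depth 1.0), attenuated
  logistically for peptides with low basal level — the inhibitor bites
  less where there is little phosphorylation to suppress;
* an extra inhibition depth on a designated signature subset of peptides,
  applied only to BRAF(V600E) samples — the class signal that the
  differential tests and PLS-DA are supposed to recover.

On the log2 scale the without-inhibitor signal of sample i, peptide j is

    b_j + τ_j·[i is tumor] + s_{series(i),j} + c_chip + ε

with lognormal noise at replicate, chip and series level; with-inhibitor
arrays additionally subtract

    δ_ij = w(b_j) · (base + extra·[i is V600E][j in signature]),
    w(b) = 1 / (1 + exp(−slope·(b − midpoint))).

A single generator seeded once drives all sampling in a fixed draw order
(baselines, elevation mask, tumor effects, signature choice, series
offsets, chip effects, then spot backgrounds and replicate noise in row
order), so identical seeds give bit-identical experiments.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .array_io import ANNOTATION_COLUMNS, ArrayExperiment, MEASUREMENT_COLUMNS
from .diffstats import SignatureSet
from .multivariate import LoocvResult


@dataclass
class SimulationConfig:
    """Study-shaped defaults: 10 V600E + 15 wild-type + 1 unknown tumors,
    4 normal-skin donors, 144 peptides of which 40 form the signature."""

    n_mutant: int = 10
    n_wildtype: int = 15
    n_unknown: int = 1
    n_normal_skin: int = 4
    n_peptides: int = 144
    n_signature: int = 40
    n_replicates: int = 3
    n_series: int = 2
    inhibitor: str = "vemurafenib"
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    tumor_effect_max_log2: float = float(np.log2(5))  # up to 5-fold elevation
    fraction_elevated: float = 0.85
    depressed_effect_max_log2: float = float(np.log2(5)) / 4
    base_inhibition_log2: float = 1.0  # ≈50% reduction
    signature_extra_inhibition_log2: float = 1.0
    basal_dependence_midpoint: float = 5.0
    basal_dependence_slope: float = 1.5
    replicate_sd: float = 0.25
    chip_sd: float = 0.15
    series_offset_sd: float = 0.3
    background_min: float = 0.5
    background_max: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_signature > self.n_peptides:
            raise ValueError("n_signature exceeds n_peptides")
        for name in ("replicate_sd", "chip_sd", "series_offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 <= self.fraction_elevated <= 1):
            raise ValueError("fraction_elevated must lie in [0, 1]")
        if self.baseline_log2_sd < 0:
            raise ValueError("baseline_log2_sd must be non-negative")
        if min(
            self.n_mutant, self.n_wildtype, self.n_peptides, self.n_replicates,
            self.n_series,
        ) < 1:
            raise ValueError("counts must be positive")
        if self.n_unknown < 0 or self.n_normal_skin < 0:
            raise ValueError("counts must be non-negative")
        if self.background_min < 0 or self.background_max < self.background_min:
            raise ValueError("background bounds invalid")


@dataclass
class GroundTruth:
    """Everything the generator knew: effects, class labels, signature."""

    peptide_ids: list[str]
    sample_classes: dict[str, str]  # sample_id → V600E / wild_type / unknown / normal
    signature: tuple[str, ...]
    baseline_log2: np.ndarray
    tumor_effect_log2: np.ndarray
    attenuation: np.ndarray  # w(b_j), in panel order
    expected_lfc: pd.DataFrame  # tumor samples × peptides, δ_ij
    config: SimulationConfig


@dataclass
class RecoveryReport:
    """How well the pipeline recovered the generator's ground truth."""

    signature_sensitivity: float
    signature_specificity: float
    n_true_signature: int
    n_called: int
    loocv_accuracy: float | None = None
    per_class_accuracy: dict | None = None


def attenuation(b, midpoint: float, slope: float):
    """Logistic weight w(b) ∈ (0, 1): low-basal peptides resist inhibition."""
    return 1.0 / (1.0 + np.exp(-slope * (np.asarray(b, dtype=float) - midpoint)))


def generate(config: SimulationConfig) -> tuple[ArrayExperiment, GroundTruth]:
    """Draw one complete experiment plus its ground truth.

    Tumor samples get paired with/without-inhibitor arrays (one chip per
    technical replicate, two arrays per chip); normal-skin donors get
    basal arrays only (replicates as arrays of a single chip).  Each
    sample belongs to one experimental series (round-robin assignment).
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    peptides = [f"PEP{j + 1:03d}" for j in range(cfg.n_peptides)]
    samples = (
        [(f"MUT{i + 1:02d}", "V600E") for i in range(cfg.n_mutant)]
        + [(f"WT{i + 1:02d}", "wild_type") for i in range(cfg.n_wildtype)]
        + [(f"UNK{i + 1:02d}", "unknown") for i in range(cfg.n_unknown)]
    )
    normals = [f"NRM{i + 1:02d}" for i in range(cfg.n_normal_skin)]
    series = [f"S{k + 1}" for k in range(cfg.n_series)]

    # -- fixed draw order ------------------------------------------------
    b = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_peptides)
    elevated = rng.random(cfg.n_peptides) < cfg.fraction_elevated
    tau_u = rng.uniform(0.0, 1.0, cfg.n_peptides)
    tau = np.where(
        elevated,
        tau_u * cfg.tumor_effect_max_log2,
        -tau_u * cfg.depressed_effect_max_log2,
    )
    sig_idx = np.sort(
        rng.choice(cfg.n_peptides, size=cfg.n_signature, replace=False)
    )
    in_sig = np.zeros(cfg.n_peptides, dtype=bool)
    in_sig[sig_idx] = True
    series_offset = rng.normal(
        0.0, cfg.series_offset_sd, (cfg.n_series, cfg.n_peptides)
    )

    w = attenuation(b, cfg.basal_dependence_midpoint, cfg.basal_dependence_slope)

    # enumerate chips deterministically, then draw one effect per chip
    chip_plan: list[tuple[str, str, int, list[tuple[int, str, int]]]] = []
    # (chip_id, sample_id, series_index, [(array_index, inhibitor, replicate)])
    for sid, _cls in samples:
        s_idx = _series_of(sid, samples, normals, cfg.n_series)
        for r in range(1, cfg.n_replicates + 1):
            chip_plan.append(
                (
                    f"{sid}-{cfg.inhibitor}-c{r}",
                    sid,
                    s_idx,
                    [(1, "none", r), (2, cfg.inhibitor, r)],
                )
            )
    for sid in normals:
        s_idx = _series_of(sid, samples, normals, cfg.n_series)
        chip_plan.append(
            (
                f"{sid}-basal",
                sid,
                s_idx,
                [(r, "none", r) for r in range(1, cfg.n_replicates + 1)],
            )
        )
    chip_effect = rng.normal(0.0, cfg.chip_sd, len(chip_plan))

    cls_of = dict(samples)
    rows: list[pd.DataFrame] = []
    for (chip_id, sid, s_idx, arrays), c_eff in zip(chip_plan, chip_effect):
        is_tumor = sid not in normals
        is_mut = cls_of.get(sid) == "V600E"
        base_log2 = b + tau * is_tumor + series_offset[s_idx] + c_eff
        for array_index, inh, rep in arrays:
            log2v = base_log2.copy()
            if inh != "none":
                log2v = log2v - w * (
                    cfg.base_inhibition_log2
                    + cfg.signature_extra_inhibition_log2 * (is_mut & in_sig)
                )
            bg = rng.uniform(cfg.background_min, cfg.background_max, cfg.n_peptides)
            eps = rng.normal(0.0, cfg.replicate_sd, cfg.n_peptides)
            linear = np.exp2(log2v + eps)
            rows.append(
                pd.DataFrame(
                    {
                        "sample_id": sid,
                        "peptide_id": peptides,
                        "chip_id": chip_id,
                        "array_index": array_index,
                        "series_id": series[s_idx],
                        "replicate": rep,
                        "inhibitor": inh,
                        "signal_raw": linear + bg,
                        "background": bg,
                    }
                )
            )
    measurements = pd.concat(rows, ignore_index=True)[MEASUREMENT_COLUMNS]

    annotations = _annotations(samples, normals)
    exp = ArrayExperiment(measurements, annotations, list(peptides))

    tumor_ids = [sid for sid, _ in samples]
    delta = np.asarray(
        [
            w
            * (
                cfg.base_inhibition_log2
                + cfg.signature_extra_inhibition_log2
                * ((cls_of[sid] == "V600E") & in_sig)
            )
            for sid in tumor_ids
        ]
    )
    truth = GroundTruth(
        peptide_ids=list(peptides),
        sample_classes={
            **{sid: cls for sid, cls in samples},
            **{sid: "normal" for sid in normals},
        },
        signature=tuple(peptides[j] for j in sig_idx),
        baseline_log2=b,
        tumor_effect_log2=tau,
        attenuation=w,
        expected_lfc=pd.DataFrame(delta, index=tumor_ids, columns=peptides),
        config=cfg,
    )
    return exp, truth


def _series_of(sid, samples, normals, n_series: int) -> int:
    order = [s for s, _ in samples] + list(normals)
    return order.index(sid) % n_series


def _annotations(samples, normals) -> pd.DataFrame:
    rows = []
    n_wt = sum(1 for _, c in samples if c == "wild_type")
    n_q61 = min(6, n_wt) if n_wt >= 6 else 0  # mirror the cohort's NRAS load
    wt_seen = 0
    for sid, cls in samples:
        nras = "wild_type"
        if cls == "wild_type":
            wt_seen += 1
            if wt_seen <= n_q61:
                nras = "Q61"
        rows.append(
            dict(
                sample_id=sid,
                tissue="melanoma",
                braf=cls if cls in ("V600E", "wild_type") else "unknown",
                nras=nras,
                cdkn2a="unknown",
                tp53="unknown",
                dtic_response="unknown",
                age="",
                sex="",
                stage="IV",
                site="",
            )
        )
    for sid in normals:
        rows.append(
            dict(
                sample_id=sid,
                tissue="normal_skin",
                braf="unknown",
                nras="unknown",
                cdkn2a="unknown",
                tp53="unknown",
                dtic_response="unknown",
                age="",
                sex="",
                stage="",
                site="",
            )
        )
    return pd.DataFrame(rows)[ANNOTATION_COLUMNS]


def truth_recovery_report(
    truth: GroundTruth,
    signature_hat: SignatureSet | list[str],
    loocv_result: LoocvResult | None = None,
) -> RecoveryReport:
    """Sensitivity/specificity of signature recovery and LOOCV accuracy.

    Sensitivity is the fraction of true signature peptides called;
    specificity the fraction of non-signature peptides not called.
    """
    called = set(
        signature_hat.peptide_ids
        if isinstance(signature_hat, SignatureSet)
        else signature_hat
    )
    panel = set(truth.peptide_ids)
    if called - panel:
        raise ValueError(
            f"called peptides outside the panel: {sorted(called - panel)[:5]}"
        )
    true_sig = set(truth.signature)
    negatives = panel - true_sig
    sens = len(called & true_sig) / len(true_sig) if true_sig else float("nan")
    spec = (
        len(negatives - called) / len(negatives) if negatives else float("nan")
    )
    report = RecoveryReport(
        signature_sensitivity=sens,
        signature_specificity=spec,
        n_true_signature=len(true_sig),
        n_called=len(called),
    )
    if loocv_result is not None:
        report.loocv_accuracy = loocv_result.overall_accuracy
        report.per_class_accuracy = dict(loocv_result.per_class_accuracy)
    return report


def ground_truth_sidecar(truth: GroundTruth) -> dict:
    """JSON-serializable dump of the ground truth for provenance sidecars."""
    return {
        "config": asdict(truth.config),
        "signature": list(truth.signature),
        "sample_classes": truth.sample_classes,
        "baseline_log2": truth.baseline_log2.tolist(),
        "tumor_effect_log2": truth.tumor_effect_log2.tolist(),
        "attenuation": truth.attenuation.tolist(),
    }
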