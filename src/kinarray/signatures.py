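"""Packaged study tables and the worked-example counts derived from them.

Three small CSV fixtures ship with the package:

* ``table1_samples.csv`` — the melanoma cohort (26 tumors, 4 normal-skin
  donors) with mutation status and clinical covariates.  Only the cohort
  *totals* (BRAF/NRAS counts, DTIC response, stage) are taken from the
  published summary table; the per-sample assignment of free-form
  covariates is a synthetic reconstruction consistent with those totals,
  since the study reports no public per-sample listing in text form.
* ``table2_signature.csv`` — the 80 kinase substrates significantly
  differentially affected by vemurafenib in at least one comparison
  (cell-line contrasts and/or melanoma tissue), with flags recording which
  comparison(s) each substrate was significant in.  The 40 substrates
  flagged in melanoma tissue are the ex-vivo vemurafenib signature.
* ``table3_pvalues.csv`` — per-cell-line t-test p-values for the EGFR,
  PDGFRβ and RAF substrates in the three melanoma cell lines
  (patient-3-post, MM200, MelJD).

The operations below reproduce the printed overlap and threshold counts:
signature size 40, cell-line/tissue overlaps 20 (MelJD vs patient-3-post)
and 8 (MelJD vs MM200), and mutation prevalences 38.5% BRAF(V600E) and
23% NRAS(Q61).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_TABLE2_FLAGS = ("absent", "significant", "significant_and_tissue")
TABLE3_CELL_LINES = ("p3post", "mm200", "meljd")


def _data_path(name: str):
    return resources.files("kinarray").joinpath("data", name)


def load_table1() -> pd.DataFrame:
    """Cohort annotation table (26 melanoma + 4 normal-skin samples)."""
    with resources.as_file(_data_path("table1_samples.csv")) as p:
        return pd.read_csv(p, dtype=str, keep_default_na=False)


def load_table2() -> pd.DataFrame:
    """Significance-flag table for the vemurafenib contrasts.

    Validates at load time that every ``significant_and_tissue`` flag (a
    bold entry in the printed table) is accompanied by tissue membership.
    """
    with resources.as_file(_data_path("table2_signature.csv")) as p:
        df = pd.read_csv(p, dtype=str, keep_default_na=False)
    df["flag_tissue"] = df["flag_tissue"].map({"true": True, "false": False})
    for col in ("flag_meljd_vs_mm200", "flag_meljd_vs_p3post"):
        bad = set(df[col]) - set(_TABLE2_FLAGS)
        if bad:
            raise ValueError(f"{col}: unknown flag level(s) {sorted(bad)}")
        inconsistent = df[(df[col] == "significant_and_tissue") & ~df["flag_tissue"]]
        if len(inconsistent):
            raise ValueError(
                "bold flag without tissue membership: "
                f"{sorted(inconsistent['peptide_id'])}"
            )
    return df


def load_table3() -> pd.DataFrame:
    """Per-cell-line p-values for the EGFR/PDGFRβ/RAF substrates."""
    with resources.as_file(_data_path("table3_pvalues.csv")) as p:
        df = pd.read_csv(p)
    pcols = ["p_p3post", "p_mm200", "p_meljd"]
    if ((df[pcols] <= 0) | (df[pcols] > 1)).to_numpy().any():
        raise ValueError("p-values outside (0, 1]")
    return df


def tissue_signature_size(table2: pd.DataFrame) -> int:
    """Number of substrates in the melanoma-tissue vemurafenib signature."""
    return int(table2["flag_tissue"].sum())


def tissue_signature_peptides(table2: pd.DataFrame) -> list[str]:
    """The signature substrate ids themselves, in table order."""
    return list(table2.loc[table2["flag_tissue"], "peptide_id"])


def cellline_tissue_overlap(table2: pd.DataFrame, comparison: str) -> int:
    """Substrates significant in a cell-line contrast *and* in tissue.

    ``comparison`` is ``meljd_vs_p3post`` or ``meljd_vs_mm200``.
    """
    col = f"flag_{comparison}"
    if col not in table2.columns:
        raise ValueError(f"unknown comparison {comparison!r}")
    return int((table2[col] == "significant_and_tissue").sum())


def count_below_alpha(
    table3: pd.DataFrame, cell_line: str, alpha: float = 0.05
) -> int:
    """Substrates with p < alpha for the named cell line in the p-value table."""
    if cell_line not in TABLE3_CELL_LINES:
        raise ValueError(
            f"unknown cell line {cell_line!r}; one of {TABLE3_CELL_LINES}"
        )
    return int((table3[f"p_{cell_line}"] < alpha).sum())


def mutation_prevalence(
    annotations: pd.DataFrame, gene: str, allele: str
) -> float:
    """Prevalence of an allele among melanoma samples, in percent.

    The denominator is the number of melanoma (tumor) samples; normal-skin
    donors are excluded.  Returns the exact percentage; use
    :func:`format_percent` for the display convention.
    """
    if gene not in ("braf", "nras"):
        raise ValueError(f"gene must be 'braf' or 'nras', got {gene!r}")
    mel = annotations[annotations["tissue"] == "melanoma"]
    if mel.empty:
        raise ValueError("no melanoma samples in annotation set")
    return 100.0 * (mel[gene] == allele).sum() / len(mel)


def format_percent(pct: float) -> str:
    """Display a prevalence rounded to the nearest half percentage point.

    38.46 → "38.5", 23.08 → "23" — integer when the half-step lands on a
    whole number.
    """
    half = round(pct * 2) / 2
    return f"{half:.1f}".rstrip("0").rstrip(".")
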