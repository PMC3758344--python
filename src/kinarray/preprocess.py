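"""From raw spot readings to basal profiles and inhibition profiles.

Two derived quantities drive all downstream analysis:

* the **basal kinase activity profile** — per sample, the vector of
  replicate-averaged log2 end-level intensities measured *without*
  inhibitor, batch-corrected by subtracting per-peptide series means
  (centering) and averaging the centered values over series;
* the **inhibition profile** — per sample, the per-peptide log-fold change
  (LFC) between paired without- and with-inhibitor incubations,
  ``LFC = log2(without) − log2(with)``, computed chip by chip (the pairing
  unit) and then averaged over a sample's chips.  Positive LFC means the
  inhibitor reduced phosphorylation.  No series centering or other
  normalization is applied to LFC values: the paired design already cancels
  chip- and batch-level offsets.

Net signals (raw minus local background) can be negative; before the log2
transform, values ≤ 0 are replaced by a small positive floor (0.01 by
default).  Positive values below the floor are left untouched — the floor
exists only to make the logarithm defined.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .array_io import ArrayExperiment
from .exceptions import CompletenessError, PairingError

logger = logging.getLogger(__name__)

DEFAULT_FLOOR = 0.01


@dataclass
class SignalMatrix:
    """Samples × peptides matrix of log2 intensities.

    ``provenance`` records which pipeline stage produced it:
    ``per_condition`` (replicate-averaged, one inhibitor condition),
    ``basal_raw`` (no series centering) or ``basal_centered``.
    """

    values: pd.DataFrame
    provenance: str = "per_condition"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class InhibitionProfile:
    """Samples × peptides matrix of paired log-fold changes (positive = inhibited)."""

    lfc: pd.DataFrame
    inhibitor: str

    @property
    def sample_ids(self) -> list[str]:
        return list(self.lfc.index)

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.lfc.columns)


def net_signal(signal_raw: float, background: float) -> float:
    """Local-background-subtracted signal; may be negative."""
    if not (math.isfinite(signal_raw) and math.isfinite(background)):
        raise ValueError("net_signal requires finite inputs")
    return signal_raw - background


def floor_log2(net, floor: float = DEFAULT_FLOOR):
    """log2 of the net signal, with non-positive values set to ``floor``.

    Accepts scalars or arrays.  Monotone non-decreasing; the identity
    composed with log2 on inputs above the floor.
    """
    if floor <= 0:
        raise ValueError(f"floor must be positive, got {floor}")
    arr = np.asarray(net, dtype=float)
    out = np.log2(np.where(arr <= 0, floor, arr))
    if np.ndim(net) == 0:
        return float(out)
    return out


def average_replicates(
    exp: ArrayExperiment,
    condition: str = "none",
    series: str | None = None,
    floor: float = DEFAULT_FLOOR,
) -> SignalMatrix:
    """Replicate-averaged log2 matrix for one inhibitor condition.

    All measurements of a (sample, peptide) cell under ``condition`` —
    across chips and replicates — are floored-log2-transformed and
    arithmetically averaged.  Restrict to one experimental series with
    ``series``.

    Raises
    ------
    CompletenessError
        If any sample present under the condition lacks measurements for
        some panel peptide (the offending cells are listed).
    """
    meas = exp.measurements
    mask = meas["inhibitor"] == condition
    if series is not None:
        mask &= meas["series_id"] == series
    sub = meas.loc[mask].copy()
    if sub.empty:
        raise CompletenessError(
            f"no measurements for condition {condition!r}"
            + (f" in series {series!r}" if series else "")
        )
    sub["log2"] = floor_log2(
        sub["signal_raw"].to_numpy() - sub["background"].to_numpy(), floor
    )
    cell_means = sub.groupby(["sample_id", "peptide_id"], sort=False)["log2"].mean()
    mat = cell_means.unstack("peptide_id")
    missing = mat.isna()
    if missing.to_numpy().any():
        cells = [
            (s, p) for s, p in zip(*np.nonzero(missing.to_numpy()))
        ]
        named = [
            (mat.index[i], mat.columns[j]) for i, j in cells[:10]
        ]
        raise CompletenessError(
            f"cells with zero replicates under {condition!r}: {named}"
        )
    panel_cols = [p for p in exp.peptide_panel if p in mat.columns]
    mat = mat.loc[sorted(mat.index), panel_cols]
    mat.index.name = "sample_id"
    return SignalMatrix(mat, provenance="per_condition")


def center_by_series(mats_by_series: Mapping[str, SignalMatrix]) -> SignalMatrix:
    """Series-center basal matrices and average them over series.

    Within each series, each peptide column has its across-sample mean
    subtracted; a sample measured in several series then gets the average of
    its centered values.  Within-series contrasts between samples are left
    unchanged by construction.
    """
    if not mats_by_series:
        raise ValueError("no series given")
    centered = []
    for sid, sm in mats_by_series.items():
        df = sm.values
        if df.empty:
            raise ValueError(f"series {sid!r} is empty")
        centered.append(df - df.mean(axis=0))
    stacked = pd.concat(centered)
    out = stacked.groupby(level=0, sort=True).mean()
    out.index.name = "sample_id"
    return SignalMatrix(out, provenance="basal_centered")


def basal_profiles(
    exp: ArrayExperiment, floor: float = DEFAULT_FLOOR, center: bool = True
) -> SignalMatrix:
    """Full basal pipeline: per-series replicate averaging, then centering.

    With ``center=False`` the replicate-averaged log2 values are pooled
    across series without batch correction (provenance ``basal_raw``).
    """
    series_ids = exp.series_ids
    per_series = {
        s: average_replicates(exp, condition="none", series=s, floor=floor)
        for s in series_ids
    }
    if not center:
        stacked = pd.concat([m.values for m in per_series.values()])
        out = stacked.groupby(level=0, sort=True).mean()
        return SignalMatrix(out, provenance="basal_raw")
    return center_by_series(per_series)


def compute_lfc(
    exp: ArrayExperiment, inhibitor: str, floor: float = DEFAULT_FLOOR
) -> InhibitionProfile:
    """Paired log-fold-change inhibition profile for one inhibitor.

    Per chip and peptide, replicate-mean floored-log2 signals are formed for
    each condition and differenced, ``LFC_chip = log2(without) − log2(with)``;
    a sample's LFC is the mean of its chip-level LFCs.

    Raises
    ------
    PairingError
        A sample has with-inhibitor arrays but no chip pairing them with
        without-inhibitor arrays.
    CompletenessError
        A paired chip lacks one condition for some peptide.
    """
    meas = exp.measurements
    treated_samples = set(meas.loc[meas["inhibitor"] == inhibitor, "sample_id"])
    if not treated_samples:
        raise PairingError(f"no measurements with inhibitor {inhibitor!r}")

    sub = meas[meas["inhibitor"].isin(["none", inhibitor])].copy()
    sub["log2"] = floor_log2(
        sub["signal_raw"].to_numpy() - sub["background"].to_numpy(), floor
    )
    # chips carrying both conditions for a sample are the pairing units
    cond_per_chip = sub.groupby(["sample_id", "chip_id"])["inhibitor"].agg(
        lambda s: frozenset(s)
    )
    paired_chips = {
        (samp, chip)
        for (samp, chip), conds in cond_per_chip.items()
        if conds == frozenset(["none", inhibitor])
    }
    unpaired = treated_samples - {s for s, _ in paired_chips}
    if unpaired:
        raise PairingError(
            f"samples with {inhibitor!r} arrays but no paired chip: "
            f"{sorted(unpaired)}"
        )

    key = pd.MultiIndex.from_frame(sub[["sample_id", "chip_id"]])
    sub = sub[key.isin(paired_chips)]
    chip_cond = (
        sub.groupby(["sample_id", "chip_id", "inhibitor", "peptide_id"], sort=False)[
            "log2"
        ]
        .mean()
        .unstack("inhibitor")
    )
    if chip_cond[["none", inhibitor]].isna().to_numpy().any():
        bad = chip_cond[chip_cond[["none", inhibitor]].isna().any(axis=1)]
        raise CompletenessError(
            f"paired chips missing one condition for cells: "
            f"{list(bad.index[:10])}"
        )
    chip_lfc = chip_cond["none"] - chip_cond[inhibitor]
    sample_lfc = chip_lfc.groupby(["sample_id", "peptide_id"], sort=False).mean()
    mat = sample_lfc.unstack("peptide_id")
    panel_cols = [p for p in exp.peptide_panel if p in mat.columns]
    mat = mat.loc[sorted(mat.index), panel_cols]
    mat.index.name = "sample_id"
    n_chips = len(paired_chips)
    logger.info(
        "LFC(%s): %d samples, %d peptides, %d paired chips",
        inhibitor,
        *mat.shape,
        n_chips,
    )
    return InhibitionProfile(mat, inhibitor=inhibitor)
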