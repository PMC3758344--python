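"""Data model and CSV I/O for paired kinase-activity array experiments.

The experimental unit is a peptide *spot measurement*: one fluorescence
reading of one of the 144 substrate peptides on one array, with full
coordinates (sample, chip, array position, experimental series, technical
replicate, inhibitor condition).  A chip carries up to four arrays, and a
sample's with-inhibitor arrays are paired with without-inhibitor arrays on
the same chip, which is what makes chip-level log-fold changes meaningful.

On disk an experiment is two UTF-8 CSV files:

* a long-format signal table with the fixed header
  ``sample_id,peptide_id,chip_id,array_index,series_id,replicate,inhibitor,signal_raw,background``
* a sample-annotation table keyed by ``sample_id`` carrying tissue type,
  mutation status (BRAF / NRAS / CDKN2A / TP53), DTIC response and free-form
  clinical covariates.

An optional panel file (one peptide id per line) pins the substrate order;
otherwise the panel is taken from the signal table in order of first
appearance.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .exceptions import (
    PairingError,
    ReferentialError,
    SchemaError,
    UniquenessError,
)

INHIBITORS = ("none", "vemurafenib", "sunitinib")

#: columns of the long-format signal table, in on-disk order
MEASUREMENT_COLUMNS = [
    "sample_id",
    "peptide_id",
    "chip_id",
    "array_index",
    "series_id",
    "replicate",
    "inhibitor",
    "signal_raw",
    "background",
]

#: columns identifying one spot measurement uniquely
MEASUREMENT_KEY = [
    "peptide_id",
    "sample_id",
    "chip_id",
    "array_index",
    "series_id",
    "replicate",
    "inhibitor",
]

ANNOTATION_COLUMNS = [
    "sample_id",
    "tissue",
    "braf",
    "nras",
    "cdkn2a",
    "tp53",
    "dtic_response",
    "age",
    "sex",
    "stage",
    "site",
]

#: categorical annotation fields and their admissible values
_CATEGORICAL_LEVELS = {
    "tissue": {"melanoma", "normal_skin"},
    "braf": {"wild_type", "V600E", "unknown"},
    "nras": {"wild_type", "Q61", "unknown"},
    "cdkn2a": {"wild_type", "mutant", "unknown"},
    "tp53": {"wild_type", "mutant", "unknown"},
    "dtic_response": {"responder", "non_responder", "unknown"},
}

_MAX_ARRAYS_PER_CHIP = 4
STANDARD_PANEL_SIZE = 144

_MEASUREMENT_DTYPES = {
    "sample_id": str,
    "peptide_id": str,
    "chip_id": str,
    "array_index": int,
    "series_id": str,
    "replicate": int,
    "inhibitor": str,
    "signal_raw": float,
    "background": float,
}


@dataclass
class ArrayExperiment:
    """A validated paired-array experiment.

    Parameters
    ----------
    measurements
        Long-format table, one row per spot measurement
        (columns :data:`MEASUREMENT_COLUMNS`).
    annotations
        One row per sample (columns :data:`ANNOTATION_COLUMNS`).
    peptide_panel
        Ordered substrate panel; every measurement's ``peptide_id`` must be
        a member.  The standard tyrosine-kinase panel has 144 entries, but
        smaller panels are accepted (toy data, tests).
    """

    measurements: pd.DataFrame
    annotations: pd.DataFrame
    peptide_panel: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.peptide_panel:
            self.peptide_panel = list(
                pd.unique(self.measurements["peptide_id"])
            )

    # -- convenience accessors -------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.measurements["sample_id"]))

    @property
    def series_ids(self) -> list[str]:
        return list(pd.unique(self.measurements["series_id"]))

    def validate(self) -> list[str]:
        """Check all structural invariants; return non-fatal warnings.

        Raises
        ------
        SchemaError
            Missing column, unknown inhibitor label, out-of-range array
            index, or a measured peptide absent from the panel.
        UniquenessError
            Duplicate measurement key tuple.
        ReferentialError
            A measured sample is missing from the annotation table.
        PairingError
            A with-inhibitor measurement has no without-inhibitor partner
            for the same sample on the same chip.
        """
        meas, ann = self.measurements, self.annotations
        _require_columns(meas, MEASUREMENT_COLUMNS, "signal table")
        _require_columns(ann, ANNOTATION_COLUMNS, "annotation table")

        bad_inh = set(meas["inhibitor"]) - set(INHIBITORS)
        if bad_inh:
            raise SchemaError(f"unknown inhibitor labels: {sorted(bad_inh)}")
        bad_idx = meas.loc[
            ~meas["array_index"].between(1, _MAX_ARRAYS_PER_CHIP), "array_index"
        ]
        if len(bad_idx):
            raise SchemaError(
                f"array_index outside 1..{_MAX_ARRAYS_PER_CHIP}: "
                f"{sorted(bad_idx.unique())}"
            )
        if (meas["background"] < 0).any():
            raise SchemaError("negative background values")

        dup = meas.duplicated(MEASUREMENT_KEY, keep=False)
        if dup.any():
            offending = meas.loc[dup, MEASUREMENT_KEY].iloc[0].tolist()
            raise UniquenessError(
                f"duplicate measurement key {tuple(offending)}"
            )

        orphans = set(meas["sample_id"]) - set(ann["sample_id"])
        if orphans:
            raise ReferentialError(
                f"samples measured but not annotated: {sorted(orphans)}"
            )

        stray = set(meas["peptide_id"]) - set(self.peptide_panel)
        if stray:
            raise SchemaError(
                f"peptides not in the panel: {sorted(stray)[:5]}"
            )

        n_arrays = meas.groupby("chip_id")["array_index"].nunique()
        crowded = n_arrays[n_arrays > _MAX_ARRAYS_PER_CHIP]
        if len(crowded):
            raise SchemaError(
                f"chips with more than {_MAX_ARRAYS_PER_CHIP} arrays: "
                f"{sorted(crowded.index)}"
            )

        # chip pairing: every (sample, chip) carrying an inhibitor condition
        # must also carry the no-inhibitor condition
        treated = meas[meas["inhibitor"] != "none"]
        untreated_pairs = set(
            map(
                tuple,
                meas.loc[
                    meas["inhibitor"] == "none", ["sample_id", "chip_id"]
                ].itertuples(index=False),
            )
        )
        for samp, chip in (
            treated[["sample_id", "chip_id"]].drop_duplicates().itertuples(index=False)
        ):
            if (samp, chip) not in untreated_pairs:
                raise PairingError(
                    f"sample {samp!r} has inhibitor arrays on chip {chip!r} "
                    "but no paired without-inhibitor array on that chip"
                )

        warnings_: list[str] = []
        # BRAF / NRAS mutations are mutually exclusive in melanoma; report
        # co-mutated samples but do not reject them
        co = ann[(ann["braf"] == "V600E") & (ann["nras"] == "Q61")]
        if len(co):
            warnings_.append(
                "samples carry both BRAF(V600E) and NRAS(Q61): "
                f"{sorted(co['sample_id'])}"
            )
        if len(self.peptide_panel) != STANDARD_PANEL_SIZE:
            warnings_.append(
                f"panel has {len(self.peptide_panel)} peptides "
                f"(standard panel: {STANDARD_PANEL_SIZE})"
            )
        return warnings_

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ArrayExperiment):
            return NotImplemented
        return (
            self.peptide_panel == other.peptide_panel
            and self.measurements.reset_index(drop=True).equals(
                other.measurements.reset_index(drop=True)
            )
            and self.annotations.reset_index(drop=True).equals(
                other.annotations.reset_index(drop=True)
            )
        )


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {missing}")


def read_experiment(
    signal_path: str | Path,
    annotation_path: str | Path,
    panel_path: str | Path | None = None,
) -> ArrayExperiment:
    """Read and validate an experiment from its two CSV files.

    Non-fatal validation findings (e.g. BRAF/NRAS co-mutation) are emitted
    as :class:`UserWarning`.
    """
    signal_path, annotation_path = Path(signal_path), Path(annotation_path)
    meas = pd.read_csv(signal_path, dtype=str, keep_default_na=False)
    _require_columns(meas, MEASUREMENT_COLUMNS, f"signal table {signal_path}")
    try:
        meas = meas.astype(_MEASUREMENT_DTYPES)[MEASUREMENT_COLUMNS]
    except ValueError as exc:
        raise SchemaError(f"malformed value in {signal_path}: {exc}") from exc

    ann = pd.read_csv(annotation_path, dtype=str, keep_default_na=False)
    _require_columns(ann, ANNOTATION_COLUMNS, f"annotation table {annotation_path}")
    ann = ann[ANNOTATION_COLUMNS]
    for col, levels in _CATEGORICAL_LEVELS.items():
        bad = set(ann[col]) - levels
        if bad:
            raise SchemaError(
                f"annotation column {col!r} has unknown level(s) {sorted(bad)}"
            )

    panel: list[str] = []
    if panel_path is not None:
        panel = [
            line.strip()
            for line in Path(panel_path).read_text().splitlines()
            if line.strip()
        ]
    exp = ArrayExperiment(meas, ann, panel)
    for msg in exp.validate():
        warnings.warn(msg, stacklevel=2)
    return exp


def write_experiment(
    exp: ArrayExperiment,
    signal_path: str | Path,
    annotation_path: str | Path,
    panel_path: str | Path | None = None,
) -> None:
    """Write an experiment to CSV; inverse of :func:`read_experiment`.

    Numeric fields are written with ``repr`` precision so the round trip is
    exact field-for-field.
    """
    exp.measurements[MEASUREMENT_COLUMNS].to_csv(
        signal_path, index=False, float_format="%.17g"
    )
    exp.annotations[ANNOTATION_COLUMNS].to_csv(annotation_path, index=False)
    if panel_path is not None:
        Path(panel_path).write_text("\n".join(exp.peptide_panel) + "\n")


def experiment_to_strings(exp: ArrayExperiment) -> tuple[str, str]:
    """Serialize an experiment to the two CSV payloads without touching disk.

    Useful for byte-level determinism checks.
    """
    sig, ann = _io.StringIO(), _io.StringIO()
    exp.measurements[MEASUREMENT_COLUMNS].to_csv(
        sig, index=False, float_format="%.17g"
    )
    exp.annotations[ANNOTATION_COLUMNS].to_csv(ann, index=False)
    return sig.getvalue(), ann.getvalue()
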