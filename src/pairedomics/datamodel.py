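"""Core data types and readers/writers shared by every pipeline stage.

The unit of analysis is the :class:`OmicsBlock`: a features x samples matrix
of log2 intensities with an explicit missingness mask, plus per-feature
metadata.  Sample annotation lives in a :class:`SampleSheet` (one row per
mass-spec sample: participant, BT/AT timepoint, sample type, batch) and
participant-level annotation (lifestyle categories, ordinal response classes,
agility measurements) in a :class:`ParticipantSheet`.

Missing values are encoded only through NaN in the value matrix; a fixed
whitelist of NA tokens is accepted at the IO boundary and anything else
non-numeric is an error, never a silent drop.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("pairedomics")

#: NA tokens accepted when parsing intensity matrices.  Fixed whitelist.
NA_TOKENS = ("", "NA", "NaN")

TIMEPOINTS = ("BT", "AT")
SAMPLE_TYPES = ("buccal", "pbmc", "plasma")
PERFORMANCE_LEVELS = ("moderate", "intermediate", "max")
SELF_ASSESSMENT_LEVELS = ("improving", "unimpaired", "stagnating", "worsening")
AGILITY_METRICS = ("flexion", "extension", "rotation")

SCHEMA_VERSION = "1.0"


class ValidationError(ValueError):
    """Raised when an input sheet or matrix violates its contract."""


# ---------------------------------------------------------------------------
# Sample and participant sheets
# ---------------------------------------------------------------------------

SAMPLE_SHEET_COLUMNS = ("sample_id", "participant_id", "timepoint",
                        "sample_type", "batch")


@dataclass
class SampleSheet:
    """One row per mass-spec sample.

    Columns: ``sample_id``, ``participant_id``, ``timepoint`` (BT/AT),
    ``sample_type`` (buccal/pbmc/plasma), ``batch``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        dup = t["sample_id"][t["sample_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicated sample_id: {sorted(set(dup))}")
        bad_tp = set(t["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValidationError(f"unknown timepoint values: {sorted(bad_tp)}")
        bad_st = set(t["sample_type"]) - set(SAMPLE_TYPES)
        if bad_st:
            raise ValidationError(f"unknown sample_type values: {sorted(bad_st)}")
        if (t["batch"].astype(str).str.len() == 0).any() or t["batch"].isna().any():
            raise ValidationError("every batch label must be non-empty")
        key = t[["participant_id", "sample_type", "timepoint"]]
        dup_key = key[key.duplicated()]
        if len(dup_key):
            raise ValidationError(
                "more than one sample per (participant, sample_type, timepoint): "
                f"{dup_key.to_dict('records')}")
        self.table = t.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, dtype=str, keep_default_na=False))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def subset(self, sample_type: str) -> pd.DataFrame:
        return self.table[self.table["sample_type"] == sample_type]

    def timepoint_of(self, sample_ids: Sequence[str]) -> pd.Series:
        m = self.table.set_index("sample_id")["timepoint"]
        unknown = [s for s in sample_ids if s not in m.index]
        if unknown:
            raise ValidationError(f"samples absent from sheet: {unknown}")
        return m.loc[list(sample_ids)]

    def batch_of(self, sample_ids: Sequence[str]) -> pd.Series:
        m = self.table.set_index("sample_id")["batch"]
        unknown = [s for s in sample_ids if s not in m.index]
        if unknown:
            raise ValidationError(f"samples absent from sheet: {unknown}")
        return m.loc[list(sample_ids)]


PARTICIPANT_SHEET_COLUMNS = (
    "participant_id", "exercise_class", "diet_class", "bmi_class",
    "performance", "self_assessment",
    "flexion_bt", "flexion_at", "extension_bt", "extension_at",
    "rotation_bt", "rotation_at",
)


@dataclass
class ParticipantSheet:
    """Participant-level lifestyle categories, ordinal response classes and
    paired agility measurements (isometric maximum strength, force units)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in PARTICIPANT_SHEET_COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"participant sheet missing columns: {missing}")
        dup = t["participant_id"][t["participant_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicated participant_id: {sorted(set(dup))}")
        bad_perf = set(t["performance"].dropna()) - set(PERFORMANCE_LEVELS)
        if bad_perf:
            raise ValidationError(f"unknown performance levels: {sorted(bad_perf)}")
        bad_sa = set(t["self_assessment"].dropna()) - set(SELF_ASSESSMENT_LEVELS)
        if bad_sa:
            raise ValidationError(f"unknown self_assessment levels: {sorted(bad_sa)}")
        agility_cols = [f"{m}_{tp}" for m in AGILITY_METRICS for tp in ("bt", "at")]
        ag = t[agility_cols].astype(float)
        if (ag <= 0).any().any():
            raise ValidationError("agility values must be positive")
        self.table = t.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ParticipantSheet":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def agility(self, timepoint: str) -> pd.DataFrame:
        """participant x metric agility values at ``bt`` or ``at``."""
        tp = timepoint.lower()
        cols = {f"{m}_{tp}": m for m in AGILITY_METRICS}
        return (self.table.set_index("participant_id")[list(cols)]
                .rename(columns=cols).astype(float))


# ---------------------------------------------------------------------------
# Omics block
# ---------------------------------------------------------------------------

@dataclass
class OmicsBlock:
    """Log2 feature x sample intensity matrix with explicit missingness.

    ``values`` is a float DataFrame (rows = feature ids, columns = sample
    ids); NaN encodes a missing cell and every present value must be finite.
    ``feature_meta`` is indexed by feature id and carries, for histone-PTM
    blocks, the precursor grouping used for relative-abundance computation.
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dups = sorted(set(v.index[v.index.duplicated()]))
            raise ValidationError(f"duplicated feature id: {dups}")
        if v.columns.duplicated().any():
            dups = sorted(set(v.columns[v.columns.duplicated()]))
            raise ValidationError(f"duplicated sample id: {dups}")
        arr = v.to_numpy(dtype=float)
        bad = np.isinf(arr)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite value at feature {v.index[i]!r}, sample {v.columns[j]!r}")
        missing_meta = v.index.difference(self.feature_meta.index)
        if len(missing_meta):
            raise ValidationError(
                f"feature_meta does not cover features: {sorted(missing_meta)}")
        self.values = v.astype(float)
        self.feature_meta = self.feature_meta.loc[v.index]

    @property
    def mask(self) -> pd.DataFrame:
        """True where a value is present."""
        return self.values.notna()

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def copy(self) -> "OmicsBlock":
        return OmicsBlock(self.values.copy(), self.feature_meta.copy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsBlock":
        return OmicsBlock(self.values[list(sample_ids)], self.feature_meta)

    def subset_features(self, feature_ids: Sequence[str]) -> "OmicsBlock":
        return OmicsBlock(self.values.loc[list(feature_ids)],
                          self.feature_meta.loc[list(feature_ids)])


def read_block(matrix_path: str | Path,
               feature_meta_path: str | Path | None,
               sheet: SampleSheet | None = None,
               *,
               linear_scale: bool = False) -> OmicsBlock:
    """Read an intensity matrix (TSV, features as rows, sample-id header).

    Cells matching an NA token become missing; any other non-numeric cell is
    an error naming its position.  With ``linear_scale`` the matrix is
    log2-transformed on the way in (zero/negative intensities become missing).
    """
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str,
                      keep_default_na=False)
    if raw.index.duplicated().any():
        dups = sorted(set(raw.index[raw.index.duplicated()]))
        raise ValidationError(f"duplicated feature id: {dups}")

    def _parse(cell: str, feat: str, samp: str) -> float:
        if cell in NA_TOKENS:
            return np.nan
        try:
            return float(cell)
        except ValueError:
            raise ValidationError(
                f"unparseable cell {cell!r} at feature {feat!r}, sample {samp!r} "
                f"(accepted NA tokens: {NA_TOKENS})") from None

    values = pd.DataFrame(
        [[_parse(raw.iat[i, j], raw.index[i], raw.columns[j])
          for j in range(raw.shape[1])] for i in range(raw.shape[0])],
        index=raw.index, columns=raw.columns, dtype=float)

    if linear_scale:
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.log2(values.where(values > 0))

    if sheet is not None:
        known = set(sheet.table["sample_id"])
        unknown = [s for s in values.columns if s not in known]
        if unknown:
            raise ValidationError(
                f"samples in matrix absent from sample sheet: {unknown}")

    if feature_meta_path is not None:
        meta = pd.read_csv(feature_meta_path, sep="\t", index_col=0)
        uncovered = values.index.difference(meta.index)
        if len(uncovered):
            raise ValidationError(
                f"feature meta file does not cover: {sorted(uncovered)}")
    else:
        meta = pd.DataFrame(index=values.index)
    return OmicsBlock(values, meta)


def write_block(block: OmicsBlock, matrix_path: str | Path,
                feature_meta_path: str | Path | None = None) -> None:
    """Write a block back to TSV; missing cells become the ``NA`` token."""
    block.values.to_csv(matrix_path, sep="\t", na_rep="NA")
    if feature_meta_path is not None:
        block.feature_meta.to_csv(feature_meta_path, sep="\t")


# ---------------------------------------------------------------------------
# Paired design
# ---------------------------------------------------------------------------

@dataclass
class Pair:
    participant_id: str
    bt_sample: str
    at_sample: str


@dataclass
class PairedDesign:
    """Per sample type, the (participant, BT sample, AT sample) pairs and the
    samples left unpaired (participants lacking the matching timepoint)."""

    pairs: dict[str, list[Pair]] = field(default_factory=dict)
    unpaired: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)
    #: (participant_id, timepoint, sample_id) triples per sample type

    def pairs_for(self, sample_type: str) -> list[Pair]:
        return self.pairs.get(sample_type, [])

    def participants(self, sample_type: str) -> list[str]:
        return [p.participant_id for p in self.pairs_for(sample_type)]

    def paired_sample_ids(self, sample_type: str) -> list[str]:
        out: list[str] = []
        for p in self.pairs_for(sample_type):
            out.extend([p.bt_sample, p.at_sample])
        return out

    def timepoint_map(self, sample_type: str) -> dict[str, str]:
        m: dict[str, str] = {}
        for p in self.pairs_for(sample_type):
            m[p.bt_sample] = "BT"
            m[p.at_sample] = "AT"
        for _, tp, sid in self.unpaired.get(sample_type, []):
            m[sid] = tp
        return m

    def n_pairs(self, sample_type: str) -> int:
        return len(self.pairs_for(sample_type))


def build_paired_design(sheet: SampleSheet) -> PairedDesign:
    """Pair every participant having both a BT and an AT sample of a type."""
    design = PairedDesign()
    for stype, grp in sheet.table.groupby("sample_type"):
        pairs: list[Pair] = []
        unpaired: list[tuple[str, str, str]] = []
        for pid, sub in grp.groupby("participant_id", sort=False):
            by_tp = sub.set_index("timepoint")["sample_id"]
            if "BT" in by_tp.index and "AT" in by_tp.index:
                pairs.append(Pair(pid, by_tp["BT"], by_tp["AT"]))
            else:
                for tp, sid in by_tp.items():
                    unpaired.append((pid, tp, sid))
        design.pairs[stype] = pairs
        design.unpaired[stype] = unpaired
    return design


# ---------------------------------------------------------------------------
# Result serialization
# ---------------------------------------------------------------------------

def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def write_results(obj: Any, path: str | Path) -> None:
    """Serialize a result: DataFrames to TSV, everything else to JSON with a
    schema version and deterministic key order."""
    path = Path(path)
    try:
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, sep="\t")
        else:
            payload = {"schema_version": SCHEMA_VERSION, "result": _jsonable(obj)}
            path.write_text(json.dumps(payload, indent=1, sort_keys=True,
                                       allow_nan=False, default=str) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc
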