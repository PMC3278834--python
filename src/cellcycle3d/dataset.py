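"""Feature tables with phase labels and class-frequency metadata.

A :class:`PhaseDataset` holds a pandas feature matrix (canonical column
order), an optional phase label per sample and the per-class counts that
drive the class-weighting rule.  Tables round-trip through CSV at full
double precision.

Phases are serialized both as names and as the integer codes 1–5 in the
order interphase, prophase, metaphase, anaphase, telophase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import ALL_FEATURES, extract_features

logger = logging.getLogger(__name__)

PHASES: tuple[str, ...] = ("interphase", "prophase", "metaphase", "anaphase", "telophase")
PHASE_CODES: dict[str, int] = {name: i + 1 for i, name in enumerate(PHASES)}
CODE_PHASES: dict[int, str] = {v: k for k, v in PHASE_CODES.items()}

_META_COLUMNS = ("stack_id", "object_id", "phase")

#: Format version stamped into written tables so trained models and tables
#: stay mutually consistent.
TABLE_VERSION = "cellcycle3d-features-1"


@dataclass
class PhaseDataset:
    """Feature matrix + labels + class-frequency metadata."""

    table: pd.DataFrame                      # meta columns + feature columns
    feature_names: tuple[str, ...] = ALL_FEATURES

    def __post_init__(self) -> None:
        missing = [c for c in self.feature_names if c not in self.table.columns]
        if missing:
            raise ValueError(f"table lacks feature columns: {missing}")
        if "phase" in self.table.columns:
            bad = set(self.table["phase"].dropna()) - set(PHASES)
            if bad:
                rows = self.table.index[self.table["phase"].isin(bad)].tolist()
                raise ValueError(f"unknown phase labels {sorted(bad)} in rows {rows}")
        else:
            self.table = self.table.assign(phase=pd.Series(pd.NA, index=self.table.index))

    # -- accessors ---------------------------------------------------------
    @property
    def X(self) -> np.ndarray:
        return self.table[list(self.feature_names)].to_numpy(dtype=float)

    @property
    def is_labelled(self) -> bool:
        return self.table["phase"].notna().all() and len(self.table) > 0

    @property
    def y(self) -> np.ndarray:
        """Phase names; raises when any sample is unlabelled."""
        if not self.is_labelled:
            raise ValueError("dataset contains unlabelled samples")
        return self.table["phase"].to_numpy()

    @property
    def y_codes(self) -> np.ndarray:
        """Integer phase codes 1–5 (interphase..telophase)."""
        return np.array([PHASE_CODES[p] for p in self.y])

    @property
    def class_counts(self) -> dict[str, int]:
        counts = self.table["phase"].dropna().value_counts()
        return {p: int(counts.get(p, 0)) for p in PHASES if counts.get(p, 0) > 0}

    def __len__(self) -> int:
        return len(self.table)

    def select_features(self, names) -> "PhaseDataset":
        """A view of the dataset restricted to the given feature columns."""
        names = tuple(names)
        unknown = [n for n in names if n not in self.feature_names]
        if unknown:
            raise ValueError(f"unknown features: {unknown}")
        cols = [c for c in _META_COLUMNS if c in self.table.columns] + list(names)
        return PhaseDataset(table=self.table[cols].copy(), feature_names=names)

    def concat(self, other: "PhaseDataset") -> "PhaseDataset":
        """Pool two datasets (identical feature lists) into one."""
        if self.feature_names != other.feature_names:
            raise ValueError("feature name lists differ")
        merged = pd.concat([self.table, other.table], ignore_index=True)
        return PhaseDataset(table=merged, feature_names=self.feature_names)


def assemble(objects, labels=None, stack_id: str = "stack0",
             levels: int = 256, displacement: int = 1,
             surface_estimator: str = "weighted") -> PhaseDataset:
    """Run all feature extractors over a list of labelled objects.

    ``labels`` optionally maps object id (or ``(stack_id, object_id)``) to a
    phase name; without it the dataset is unlabelled (prediction mode).
    Objects whose extraction fails (e.g. all GLCM directions empty) are
    excluded with a logged reason rather than imputed.
    """
    label_of = {}
    if labels is not None:
        for key, phase in dict(labels).items():
            oid = key[1] if isinstance(key, tuple) else key
            sid = key[0] if isinstance(key, tuple) else stack_id
            if phase not in PHASES:
                raise ValueError(f"unknown phase {phase!r} for object {oid}")
            if (sid, oid) in label_of:
                raise ValueError(f"duplicate label for object {(sid, oid)}")
            label_of[(sid, oid)] = phase
        known = {(stack_id, o.object_id) for o in objects}
        unknown = set(label_of) - known
        if unknown:
            raise ValueError(f"labels refer to unknown object ids: {sorted(unknown)}")

    rows = []
    for obj in objects:
        try:
            feats = extract_features(obj, levels=levels, displacement=displacement,
                                     surface_estimator=surface_estimator)
        except ValueError as exc:
            logger.warning("object %s excluded from dataset: %s", obj.object_id, exc)
            continue
        row = {"stack_id": stack_id, "object_id": obj.object_id,
               "phase": label_of.get((stack_id, obj.object_id), pd.NA)}
        row.update(feats)
        rows.append(row)
    table = pd.DataFrame(rows, columns=list(_META_COLUMNS) + list(ALL_FEATURES)
                         if rows else list(_META_COLUMNS) + list(ALL_FEATURES))
    return PhaseDataset(table=table)


def from_arrays(X: np.ndarray, y=None, feature_names=None) -> PhaseDataset:
    """Build a dataset directly from a numeric matrix (synthetic feature
    studies, tests).  ``y`` may hold phase names or codes 1–5."""
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = tuple(f"f{i:02d}" for i in range(X.shape[1]))
    table = pd.DataFrame(X, columns=list(feature_names))
    table.insert(0, "stack_id", "mem")
    table.insert(1, "object_id", np.arange(1, len(table) + 1))
    if y is not None:
        names = [CODE_PHASES[int(v)] if not isinstance(v, str) else v for v in y]
        table.insert(2, "phase", names)
    return PhaseDataset(table=table, feature_names=tuple(feature_names))


def write_table(path, data: PhaseDataset) -> None:
    """Write the feature table as CSV at full double precision."""
    out = data.table.copy()
    out.insert(0, "version", TABLE_VERSION)
    out.insert(3, "phase_code",
               [PHASE_CODES.get(p, 0) if pd.notna(p) else 0 for p in out["phase"]])
    out.to_csv(path, index=False, float_format="%.17g")


def read_table(path) -> PhaseDataset:
    """Read a feature table written by :func:`write_table` (or any CSV with
    the canonical header).  A missing ``phase`` column loads as unlabelled."""
    raw = pd.read_csv(path, float_precision="round_trip")
    for col in ("version", "phase_code"):
        if col in raw.columns:
            raw = raw.drop(columns=col)
    feature_cols = [c for c in raw.columns if c not in _META_COLUMNS]
    unknown = [c for c in feature_cols if c not in ALL_FEATURES]
    if unknown:
        raise ValueError(f"unknown columns in feature table: {unknown}")
    names = tuple(c for c in ALL_FEATURES if c in feature_cols)
    if "phase" in raw.columns:
        bad_rows = raw.index[raw["phase"].notna() & ~raw["phase"].isin(PHASES)]
        if len(bad_rows):
            raise ValueError(
                f"malformed phase label {raw.loc[bad_rows[0], 'phase']!r} "
                f"in row {int(bad_rows[0])}"
            )
    return PhaseDataset(table=raw, feature_names=names)
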