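"""Feature tables and the three-stage descriptor filter.

A :class:`FeatureTable` is a residues-by-descriptors matrix plus a class
column (binary label or numeric criticality target) and optional instance
identifiers, readable/writable as CSV or ARFF.

Filtering proceeds in a fixed order, each stage exposed both as an
sklearn-style transformer and as a convenience function on FeatureTables:

1. constant removal — descriptors that never vary carry no information;
2. Spearman redundancy — scanning descriptors in column order, any
   descriptor whose |rho| with an already-retained one reaches the
   threshold (default 0.95) is dropped;
3. information-gain relevance — descriptors whose MDLP-discretized
   information gain against the binary class is zero are dropped.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import SelectorMixin

from ._mdlp import information_gain

log = logging.getLogger(__name__)


@dataclass
class FeatureTable:
    """Descriptor matrix + target + optional instance ids."""

    X: pd.DataFrame
    y: pd.Series
    ids: pd.DataFrame | None = None
    target_type: str = "nominal"  # "nominal" (binary label) or "numeric"

    def __post_init__(self):
        if len(self.X) != len(self.y):
            raise ValueError("X and y lengths differ")
        if self.X.columns.duplicated().any():
            dupes = self.X.columns[self.X.columns.duplicated()].tolist()
            raise ValueError(f"duplicate descriptor names: {dupes}")
        if self.X.isna().any().any():
            raise ValueError(
                "missing values in descriptor matrix; impute or drop rows first"
            )
        if self.target_type not in ("nominal", "numeric"):
            raise ValueError("target_type must be 'nominal' or 'numeric'")

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def n_instances(self) -> int:
        return len(self.X)

    def select(self, names) -> "FeatureTable":
        return FeatureTable(self.X.loc[:, list(names)].copy(), self.y.copy(),
                            None if self.ids is None else self.ids.copy(),
                            self.target_type)

    def to_frame(self) -> pd.DataFrame:
        parts = [] if self.ids is None else [self.ids.reset_index(drop=True)]
        parts.append(self.X.reset_index(drop=True))
        frame = pd.concat(parts, axis=1)
        frame["class"] = self.y.reset_index(drop=True)
        return frame


ID_COLUMNS = ("protein", "residue")


def _split_frame(frame: pd.DataFrame, target_type: str | None) -> FeatureTable:
    if "class" not in frame.columns:
        raise ValueError("feature table needs a 'class' column")
    y = frame["class"]
    ids = frame.loc[:, [c for c in ID_COLUMNS if c in frame.columns]]
    X = frame.drop(columns=["class", *ids.columns])
    non_num = [c for c in X.columns if not pd.api.types.is_numeric_dtype(X[c])]
    if non_num:
        raise ValueError(f"non-numeric descriptor columns: {non_num}")
    if target_type is None:
        target_type = "numeric" if pd.api.types.is_numeric_dtype(y) else "nominal"
    return FeatureTable(X, y, ids if len(ids.columns) else None, target_type)


def read_feature_table(path, fmt: str | None = None) -> FeatureTable:
    path = str(path)
    if fmt is None:
        fmt = "arff" if path.lower().endswith(".arff") else "csv"
    if fmt == "csv":
        return _split_frame(pd.read_csv(path), None)
    if fmt == "arff":
        with open(path) as fh:
            return _read_arff(fh.read())
    raise ValueError(f"unknown format {fmt!r}")


def write_feature_table(table: FeatureTable, path, fmt: str | None = None) -> None:
    path = str(path)
    if fmt is None:
        fmt = "arff" if path.lower().endswith(".arff") else "csv"
    if fmt == "csv":
        table.to_frame().to_csv(path, index=False)
    elif fmt == "arff":
        with open(path, "w") as fh:
            fh.write(to_arff(table))
    else:
        raise ValueError(f"unknown format {fmt!r}")


# --- minimal dense ARFF (numeric descriptors, nominal or numeric class) ------

def to_arff(table: FeatureTable, relation: str = "critres") -> str:
    lines = [f"@RELATION {relation}", ""]
    if table.ids is not None:
        for c in table.ids.columns:
            lines.append(f"@ATTRIBUTE {c} STRING")
    for name in table.descriptor_names:
        lines.append(f"@ATTRIBUTE {name} NUMERIC")
    if table.target_type == "nominal":
        values = ",".join(sorted(map(str, pd.unique(table.y))))
        lines.append(f"@ATTRIBUTE class {{{values}}}")
    else:
        lines.append("@ATTRIBUTE class NUMERIC")
    lines.append("")
    lines.append("@DATA")
    frame = table.to_frame()
    for _, row in frame.iterrows():
        lines.append(",".join(_arff_cell(v) for v in row))
    return "\n".join(lines) + "\n"


def _arff_cell(v) -> str:
    if isinstance(v, str):
        return f"'{v}'" if ("," in v or " " in v) else v
    return repr(float(v)) if isinstance(v, (float, np.floating)) else str(v)


_ATTR_RE = re.compile(r"@attribute\s+('?)([^\s']+)\1\s+(.+)", re.IGNORECASE)


def _read_arff(text: str) -> FeatureTable:
    names, kinds = [], []
    rows = []
    in_data = False
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        if in_data:
            rows.append([_parse_cell(c) for c in line.split(",")])
            continue
        low = line.lower()
        if low.startswith("@data"):
            in_data = True
        elif low.startswith("@attribute"):
            m = _ATTR_RE.match(line)
            if not m:
                raise ValueError(f"malformed @attribute line: {raw!r}")
            names.append(m.group(2))
            spec = m.group(3).strip()
            if spec.startswith("{"):
                kinds.append("nominal")
            elif spec.lower() in ("numeric", "real", "integer"):
                kinds.append("numeric")
            elif spec.lower() == "string":
                kinds.append("string")
            else:
                raise ValueError(f"unsupported attribute type {spec!r}")
        elif low.startswith("@relation"):
            continue
    if not in_data or not names:
        raise ValueError("malformed ARFF: missing @attribute or @data section")
    frame = pd.DataFrame(rows, columns=names)
    for name, kind in zip(names, kinds):
        if kind == "numeric":
            frame[name] = pd.to_numeric(frame[name])
    target_type = "numeric" if kinds[names.index("class")] == "numeric" else "nominal"
    return _split_frame(frame, target_type)


def _parse_cell(c: str):
    c = c.strip()
    if len(c) >= 2 and c[0] == c[-1] and c[0] in "'\"":
        return c[1:-1]
    return c


# --- filter transformers ------------------------------------------------------

class _NamedSelector(SelectorMixin, BaseEstimator):
    """Shared plumbing: DataFrame-aware fit input, support mask, name report."""

    def _prepare(self, X):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            self.feature_names_in_ = np.asarray(
                [f"x{i}" for i in range(values.shape[1])], dtype=object
            )
        if values.ndim != 2:
            raise ValueError("expected a 2D descriptor matrix")
        self.n_features_in_ = values.shape[1]
        return values

    def _finish(self, support: np.ndarray):
        self.support_ = support
        self.dropped_names_ = [
            str(n) for n, keep in zip(self.feature_names_in_, support) if not keep
        ]
        return self

    def _get_support_mask(self):
        return self.support_

    def report(self) -> dict:
        return {
            "filter": type(self).__name__,
            "n_in": int(self.n_features_in_),
            "n_kept": int(self.support_.sum()),
            "dropped": list(self.dropped_names_),
        }


class ConstantFeatureFilter(_NamedSelector):
    """Drop descriptors that do not vary across instances."""

    def fit(self, X, y=None):
        values = self._prepare(X)
        if values.shape[0] < 1:
            raise ValueError("need at least one instance")
        support = (values.max(axis=0) - values.min(axis=0)) > 0
        return self._finish(support)


class SpearmanRedundancyFilter(_NamedSelector):
    """Drop descriptors rank-correlated with an earlier retained one.

    Descriptors are scanned in column order; the first of a correlated
    group is kept.  Constant columns (undefined rho) are treated as
    uncorrelated and flagged — they should have been removed upstream.
    """

    def __init__(self, threshold: float = 0.95):
        self.threshold = threshold

    def fit(self, X, y=None):
        values = self._prepare(X)
        n, m = values.shape
        if n < 3:
            raise ValueError("need at least 3 instances for rank correlation")
        constant = (values.max(axis=0) - values.min(axis=0)) == 0
        if constant.any():
            log.warning(
                "%d constant columns reached the Spearman filter", int(constant.sum())
            )
        # ranks once, correlations via Pearson on ranks
        ranks = pd.DataFrame(values).rank().to_numpy()
        ranks = (ranks - ranks.mean(axis=0)) / np.where(
            ranks.std(axis=0) > 0, ranks.std(axis=0), 1.0
        )
        support = np.zeros(m, dtype=bool)
        kept: list[int] = []
        for j in range(m):
            if constant[j]:
                support[j] = True  # rho treated as 0: never redundant
                kept.append(j)
                continue
            redundant = False
            for k in kept:
                if constant[k]:
                    continue
                rho = float(np.mean(ranks[:, j] * ranks[:, k]))
                if abs(rho) >= self.threshold:
                    redundant = True
                    break
            support[j] = not redundant
            if not redundant:
                kept.append(j)
        return self._finish(support)


class InfoGainFilter(_NamedSelector):
    """Drop descriptors with zero MDLP information gain against a binary class."""

    def fit(self, X, y):
        values = self._prepare(X)
        y = np.asarray(y)
        if pd.api.types.is_float_dtype(y) and len(np.unique(y)) > 10:
            raise ValueError(
                "information-gain filter needs a nominal class; "
                "numeric targets are not supported"
            )
        self.gains_ = np.array(
            [information_gain(values[:, j], y) for j in range(values.shape[1])]
        )
        return self._finish(self.gains_ > 0)


# --- FeatureTable-level convenience wrappers ---------------------------------

def _apply(table: FeatureTable, flt: _NamedSelector, needs_y: bool):
    flt.fit(table.X, table.y if needs_y else None)
    kept = [n for n, keep in zip(table.descriptor_names, flt.support_) if keep]
    return table.select(kept), flt.report()


def remove_useless(table: FeatureTable):
    """Constant-descriptor removal; returns (filtered table, report)."""
    return _apply(table, ConstantFeatureFilter(), needs_y=False)


def spearman_redundancy_filter(table: FeatureTable, threshold: float = 0.95):
    return _apply(table, SpearmanRedundancyFilter(threshold=threshold), needs_y=False)


def information_gain_filter(table: FeatureTable):
    if table.target_type != "nominal":
        raise ValueError(
            "information-gain filter requires a binary class column; "
            "use a binary-labeled dataset"
        )
    return _apply(table, InfoGainFilter(), needs_y=True)


def filter_pipeline(table: FeatureTable, spearman_threshold: float = 0.95):
    """Constant -> Spearman -> information gain, with a combined report."""
    t1, r1 = remove_useless(table)
    t2, r2 = spearman_redundancy_filter(t1, spearman_threshold)
    if table.target_type == "nominal":
        t3, r3 = information_gain_filter(t2)
    else:
        t3, r3 = t2, {"filter": "InfoGainFilter", "skipped": "numeric target"}
    return t3, {"stages": [r1, r2, r3]}
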