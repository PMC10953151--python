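"""File formats and model (de)serialization.

Feature matrices are TSV/CSV (dialect picked by extension): first column
sample ids, header row feature ids.  Group structures use the GMT
dialect: one set per line, ``name<TAB>description<TAB>member...``.
Models round-trip through a versioned JSON document.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .spike_slab import NsslassoModel
from .stacking import FoldPlan, GroupStructure, StackedModel, SubModel

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_outcome",
    "read_gmt",
    "write_gmt",
    "save_model",
    "load_model",
    "align_samples",
]

SCHEMA_VERSION = 1


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Numeric matrix with sample ids as index and feature ids as columns.

    Raises on non-numeric cells (naming the offending row/column) and on
    duplicated feature ids; row order is preserved.
    """
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    names = header[1:]  # first column holds sample ids
    if not names:
        raise ValueError(f"{path}: no feature columns (missing header?)")
    seen: set[str] = set()
    dup = [n for n in names if n in seen or seen.add(n)]
    if dup:
        raise ValueError(f"{path}: duplicated feature id(s): {dup[:5]}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value at row {bad[0]!r}, column {col!r}"
            )
        df[col] = coerced
    if df.isna().any().any():
        row, col = next(
            (r, c) for c in df.columns for r in df.index[df[c].isna()]
        )
        raise ValueError(f"{path}: missing value at row {row!r}, column {col!r}")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep=_sep_for(path))


def read_outcome(path: str | Path) -> pd.Series:
    """Outcome vector: two columns (sample id, value) with a header."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.shape[1] != 1:
        raise ValueError(f"{path}: expected exactly one outcome column")
    return pd.to_numeric(df.iloc[:, 0])


def align_samples(X: pd.DataFrame, y: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    """Match X and y by sample id (not row order); mismatches are fatal."""
    missing_in_y = [s for s in X.index if s not in y.index]
    missing_in_x = [s for s in y.index if s not in X.index]
    if missing_in_y or missing_in_x:
        raise ValueError(
            "sample ids do not match: "
            f"{len(missing_in_y)} only in X (e.g. {missing_in_y[:3]}), "
            f"{len(missing_in_x)} only in y (e.g. {missing_in_x[:3]})"
        )
    return X, y.loc[X.index]


def read_gmt(path: str | Path) -> GroupStructure:
    """Parse a GMT gene-set file into an order-preserving GroupStructure.

    Duplicate members within a set are deduplicated with a warning;
    duplicate set names and lines with fewer than three fields are errors.
    """
    groups: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected name, description and at "
                    f"least one member ({len(fields)} field(s) found)"
                )
            name, _desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
            if name in groups:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen: set[str] = set()
            unique = []
            for m in members:
                if m in seen:
                    continue
                seen.add(m)
                unique.append(m)
            if len(unique) < len(members):
                warnings.warn(
                    f"{path}:{lineno}: set {name!r} lists duplicate members; "
                    "deduplicated", stacklevel=2,
                )
            groups[name] = unique
    return GroupStructure(groups)


def write_gmt(groups: GroupStructure, path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in groups.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def _stacked_to_dict(model: StackedModel) -> dict:
    return {
        "kind": "stacked",
        "w0": model.w0,
        "weights": model.weights.tolist(),
        "super_learner": model.super_learner,
        "family": model.family,
        "fold_plan": {
            "K": model.fold_plan.K,
            "assignment": model.fold_plan.assignment.tolist(),
            "seed": model.fold_plan.seed,
            "stratified": model.fold_plan.stratified,
        },
        "info": {k: v for k, v in model.info.items()
                 if isinstance(v, (int, float, str, bool))},
        "p_inclusion": (np.asarray(model.info["p"]).tolist()
                        if "p" in model.info else None),
        "sub_models": [
            {
                "group_id": s.group_id,
                "learner": s.learner,
                "feature_names": s.feature_names,
                "intercept": s.intercept,
                "coefficients": s.coefficients.tolist(),
                "family": s.family,
                "cv_auc": s.cv_auc,
            }
            for s in model.sub_models
        ],
    }


def _stacked_from_dict(d: dict) -> StackedModel:
    fp = d["fold_plan"]
    plan = FoldPlan(K=fp["K"], assignment=np.asarray(fp["assignment"], dtype=np.int64),
                    seed=fp["seed"], stratified=fp["stratified"])
    subs = [
        SubModel(
            group_id=s["group_id"], learner=s["learner"],
            feature_names=list(s["feature_names"]),
            intercept=float(s["intercept"]),
            coefficients=np.asarray(s["coefficients"], dtype=np.float64),
            family=s["family"], cv_auc=s.get("cv_auc"),
        )
        for s in d["sub_models"]
    ]
    info = dict(d.get("info", {}))
    if d.get("p_inclusion") is not None:
        info["p"] = np.asarray(d["p_inclusion"], dtype=np.float64)
    return StackedModel(
        w0=float(d["w0"]), weights=np.asarray(d["weights"], dtype=np.float64),
        sub_models=subs, super_learner=d["super_learner"], family=d["family"],
        fold_plan=plan, info=info,
    )


def save_model(model: StackedModel | NsslassoModel, path: str | Path) -> None:
    """Serialize a fitted model to versioned JSON."""
    if isinstance(model, StackedModel):
        doc = _stacked_to_dict(model)
    elif isinstance(model, NsslassoModel):
        doc = {"kind": "nsslasso", **model.to_dict()}
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    doc["schema_version"] = SCHEMA_VERSION
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path: str | Path) -> StackedModel | NsslassoModel:
    """Load a model saved by :func:`save_model`; predictions round-trip
    to within 1e-12."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: not a valid model file: {exc}") from exc
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"{path}: schema version {version!r} not supported "
            f"(expected {SCHEMA_VERSION})"
        )
    if doc["kind"] == "stacked":
        return _stacked_from_dict(doc)
    if doc["kind"] == "nsslasso":
        return NsslassoModel.from_dict(doc)
    raise ValueError(f"{path}: unknown model kind {doc['kind']!r}")
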