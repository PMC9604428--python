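"""Readers and writers for bilateral expression tables and result artifacts.

The canonical on-disk dialect is a long-format TSV/CSV with columns
``gene_id, individual_id, side, value`` and optional ``replicate, group,
sex, position`` columns; Ct tables use ``ct`` in place of ``value`` and
carry a designated reference gene.  Sides are normalized to ``L``/``R``
and are exchangeable: no orientation semantics attach to either label.
Technical replicate wells are averaged before any analysis; missing
left/right partners are dropped and reported, never imputed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .core import BilateralMatrix

__all__ = [
    "RunConfig",
    "read_bilateral_table",
    "read_ct_table",
    "write_bilateral_table",
    "write_results",
    "load_run_config",
]

_SIDE_ALIASES = {
    "l": "L", "left": "L", "L": "L",
    "r": "R", "right": "R", "R": "R",
}

_MODES = (
    "per-gene", "pooled-group", "per-individual", "pairwise",
    "subset", "trait-model", "simulate",
)


@dataclass
class RunConfig:
    """Validated run configuration for the command-line pipeline."""

    mode: str
    input_path: Optional[str] = None
    output_dir: str = "."
    log_base: str = "2"
    seed: int = 0
    fdr_alpha: float = 0.05
    reference_gene: Optional[str] = None
    verbosity: str = "info"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {_MODES}")
        if self.mode not in ("simulate",) and self.input_path is None:
            raise ValueError(f"mode {self.mode!r} requires an input path")
        if not (0 < self.fdr_alpha < 1):
            raise ValueError("fdr_alpha must lie in (0, 1)")


def load_run_config(path: Union[str, Path]) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    fields = set(RunConfig.__dataclass_fields__) - {"extra"}
    known = {k: v for k, v in data.items() if k in fields}
    extra = {k: v for k, v in data.items() if k not in fields}
    return RunConfig(**known, extra=extra)


def _read_table(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def _normalize_sides(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    sides = df["side"].astype(str).str.strip()
    mapped = sides.map(lambda s: _SIDE_ALIASES.get(s.lower(), None))
    if mapped.isna().any():
        bad = sorted(sides[mapped.isna()].unique())
        raise ValueError(f"unrecognized side labels: {bad}")
    df["side"] = mapped
    return df


def _average_replicates(df: pd.DataFrame, value_col: str) -> pd.DataFrame:
    keys = ["gene_id", "individual_id", "side"]
    meta_cols = [c for c in ("group", "sex", "position") if c in df.columns]
    agg = {value_col: "mean", **{c: "first" for c in meta_cols}}
    return df.groupby(keys, as_index=False, sort=False).agg(agg)


def _pivot_bilateral(
    df: pd.DataFrame, value_col: str, log_base: str
) -> BilateralMatrix:
    wide = df.pivot_table(
        index="gene_id", columns=["individual_id", "side"], values=value_col,
        sort=False,
    )
    individuals = list(dict.fromkeys(df["individual_id"]))
    genes = list(wide.index)

    incomplete = 0
    left_cols, right_cols = {}, {}
    for ind in individuals:
        for side, store in (("L", left_cols), ("R", right_cols)):
            store[ind] = wide[ind][side] if (ind, side) in wide.columns else pd.Series(
                np.nan, index=wide.index
            )
    L = pd.DataFrame(left_cols, index=wide.index)
    R = pd.DataFrame(right_cols, index=wide.index)
    missing = L.isna() | R.isna()
    incomplete = int(missing.values.sum())
    if incomplete:
        bad_genes = list(L.index[missing.any(axis=1)])
        warnings.warn(
            f"{incomplete} (gene, individual) pair(s) missing a side; "
            f"dropping gene(s) {bad_genes}",
            UserWarning,
            stacklevel=3,
        )
        keep = ~missing.any(axis=1)
        L, R = L[keep], R[keep]
        genes = list(L.index)
    if len(genes) == 0:
        raise ValueError("no complete left/right gene rows remain")

    meta = {}
    first = df.drop_duplicates("individual_id").set_index("individual_id")
    for col, name in (("group", "group_labels"), ("sex", "sex_labels"), ("position", "position")):
        if col in df.columns:
            meta[name] = first.loc[individuals, col].to_numpy()
    return BilateralMatrix(
        gene_ids=genes,
        left=L[individuals].to_numpy(),
        right=R[individuals].to_numpy(),
        log_base=log_base,  # type: ignore[arg-type]
        individual_ids=list(individuals),
        **meta,
    )


def read_bilateral_table(
    path: Union[str, Path],
    log_base: str = "natural",
    value_col: str = "value",
) -> BilateralMatrix:
    """Read a long-format bilateral log-expression table.

    Required columns: ``gene_id, individual_id, side, value``; optional
    ``replicate`` (wells averaged), ``group``, ``sex``, ``position``.
    Side labels are case-insensitive (``left``/``l``/``L``).  Pairs missing
    one side are dropped with a reported count.
    """
    df = _read_table(path)
    required = {"gene_id", "individual_id", "side", value_col}
    if not required.issubset(df.columns):
        raise ValueError(f"missing required columns: {sorted(required - set(df.columns))}")
    df = _normalize_sides(df)
    df = _average_replicates(df, value_col)
    return _pivot_bilateral(df, value_col, log_base)


def read_ct_table(
    path: Union[str, Path],
    reference_gene: str = "18S",
) -> BilateralMatrix:
    """Read an RT-qPCR Ct table and normalize to a reference gene.

    Technical replicates are averaged first; then dCt = Ct_gene - Ct_ref is
    formed per side.  Individuals lacking the reference on either side are
    dropped with a warning; the reference itself (dCt identically 0) is
    excluded from the returned panel.  Values are log2-scale (dCt), so
    ``log_base`` is "2".
    """
    df = _read_table(path)
    value_col = "ct" if "ct" in df.columns else "value"
    required = {"gene_id", "individual_id", "side", value_col}
    if not required.issubset(df.columns):
        raise ValueError(f"missing required columns: {sorted(required - set(df.columns))}")
    df = _normalize_sides(df)
    df = _average_replicates(df, value_col)

    ref = df[df["gene_id"] == reference_gene].set_index(["individual_id", "side"])[value_col]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} not found")
    panel = df[df["gene_id"] != reference_gene].copy()
    key = list(zip(panel["individual_id"], panel["side"]))
    has_ref = [k in ref.index for k in key]
    dropped = sorted(set(panel.loc[[not h for h in has_ref], "individual_id"]))
    if dropped:
        warnings.warn(
            f"dropping individual(s) without reference-gene wells: {dropped}",
            UserWarning,
            stacklevel=2,
        )
        panel = panel[~panel["individual_id"].isin(dropped)]
        key = list(zip(panel["individual_id"], panel["side"]))
    panel[value_col] = panel[value_col].to_numpy() - ref.loc[key].to_numpy()
    return _pivot_bilateral(panel, value_col, log_base="2")


def write_bilateral_table(M: BilateralMatrix, path: Union[str, Path]) -> None:
    """Write a BilateralMatrix as a long-format TSV (full precision)."""
    rows = []
    for gi, g in enumerate(M.gene_ids):
        for j, ind in enumerate(M.individual_ids):
            for side, mat in (("L", M.left), ("R", M.right)):
                row = {
                    "gene_id": g, "individual_id": ind, "side": side,
                    "value": repr(float(mat[gi, j])),
                }
                if M.group_labels is not None:
                    row["group"] = M.group_labels[j]
                if M.sex_labels is not None:
                    row["sex"] = M.sex_labels[j]
                if M.position is not None:
                    row["position"] = M.position[j]
                rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(
    results: dict,
    outdir: Union[str, Path],
    config: Optional[dict] = None,
    seed: Optional[int] = None,
) -> dict:
    """Write tabular results as TSV and mappings as JSON, with a manifest.

    ``results`` maps artifact names to DataFrames (written as
    ``<name>.tsv``) or JSON-serializable mappings (``<name>.json``).  The
    manifest records every artifact with its sha256 checksum plus the run
    config and seed, and is itself written as ``manifest.json``.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {outdir} is not writable: {exc}") from exc

    manifest = {"artifacts": {}, "config": config or {}, "seed": seed}
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            path = outdir / f"{name}.tsv"
            obj.to_csv(path, sep="\t", index=False)
        else:
            path = outdir / f"{name}.json"
            path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))
        manifest["artifacts"][name] = {
            "file": path.name,
            "sha256": _sha256(path),
        }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=_jsonify)
    )
    return manifest


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
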