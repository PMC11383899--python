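"""Readers and writers for the pipeline's file formats.

CSV for matrices (comma, header row, UTF-8), TSV for result tables, GMT for
gene sets, YAML for configuration. Readers validate schemas strictly and
raise :class:`~chemoscreen.errors.ParseError` naming the file and offending
column or line; write-then-read round-trips values exactly (floats are
serialized with 17 significant digits).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError
from .migration import DEFAULT_SUBSETS, AttractantMeta, MigrationWell
from .secretome import SecretomeProfile
from .signatures import ExpressionMatrix, SignatureDef

__all__ = [
    "read_wells",
    "write_wells",
    "read_meta",
    "write_meta",
    "read_npx",
    "write_npx",
    "read_lod",
    "write_lod",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_composites",
    "write_composites",
    "read_labels",
    "write_labels",
    "write_table",
]

_FLOAT_FMT = "%.17g"

_WELL_FIXED = ["well_id", "attractant_id", "attractant_class", "donor_id", "replicate",
               "bead_events", "beads_added"]
_META_COLS = ["attractant_id", "hpv_status", "site", "fibroblast_depleted"]
_NPX_FIXED = ["sample_id", "source", "site"]


def _read_csv(path: str | Path, sep: str = ",") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        return pd.read_csv(path, sep=sep, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise ParseError(f"{path}: {exc}") from exc


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: Path | str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")


def _no_duplicates(values: pd.Series, path: Path | str, what: str) -> None:
    dup = values[values.duplicated()]
    if not dup.empty:
        line = int(dup.index[0]) + 2  # header is line 1
        raise ParseError(f"{path}: duplicate {what} {dup.iloc[0]!r} at line {line}")


def _numeric(df: pd.DataFrame, cols: Iterable[str], path: Path | str) -> pd.DataFrame:
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise ParseError(
                f"{path}: non-numeric value {df.loc[bad.idxmax(), c]!r} "
                f"in column {c!r} at line {line}"
            )
        df[c] = coerced
    return df


# ---------------------------------------------------------------- wells


def read_wells(path: str | Path, subsets: Sequence[str] = DEFAULT_SUBSETS) -> list[MigrationWell]:
    """One row per well: fixed columns then one event-count column per subset."""
    df = _read_csv(path)
    _require_columns(df, _WELL_FIXED, path)
    _no_duplicates(df["well_id"], path, "well_id")
    subset_cols = [s for s in subsets if s in df.columns]
    if not subset_cols:
        raise ParseError(f"{path}: no subset event-count columns found")
    df = _numeric(df, ["replicate", "bead_events", "beads_added", *subset_cols], path)
    wells = []
    for _, row in df.iterrows():
        wells.append(
            MigrationWell(
                well_id=str(row.well_id),
                attractant_id=str(row.attractant_id),
                attractant_class=str(row.attractant_class),
                donor_id=str(row.donor_id),
                replicate=int(row.replicate),
                subset_events={s: int(row[s]) for s in subset_cols if pd.notna(row[s])},
                bead_events=int(row.bead_events),
                beads_added=int(row.beads_added),
            )
        )
    return wells


def write_wells(wells: Sequence[MigrationWell], path: str | Path) -> None:
    subsets = sorted({s for w in wells for s in w.subset_events}, key=lambda s: (
        DEFAULT_SUBSETS.index(s) if s in DEFAULT_SUBSETS else len(DEFAULT_SUBSETS), s))
    rows = []
    for w in wells:
        row = {
            "well_id": w.well_id,
            "attractant_id": w.attractant_id,
            "attractant_class": w.attractant_class.value,
            "donor_id": w.donor_id,
            "replicate": w.replicate,
            "bead_events": w.bead_events,
            "beads_added": w.beads_added,
        }
        for s in subsets:
            row[s] = w.subset_events.get(s, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------- meta


def read_meta(path: str | Path) -> list[AttractantMeta]:
    df = _read_csv(path)
    _require_columns(df, _META_COLS, path)
    _no_duplicates(df["attractant_id"], path, "attractant_id")
    out = []
    for _, row in df.iterrows():
        dep = row.fibroblast_depleted
        out.append(
            AttractantMeta(
                attractant_id=str(row.attractant_id),
                hpv_status=str(row.hpv_status),
                site=str(row.site),
                fibroblast_depleted=bool(dep) if isinstance(dep, (bool, np.bool_))
                else str(dep).strip().lower() in ("true", "1", "yes"),
            )
        )
    return out


def write_meta(meta: Sequence[AttractantMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "attractant_id": m.attractant_id,
                "hpv_status": m.hpv_status,
                "site": m.site,
                "fibroblast_depleted": m.fibroblast_depleted,
            }
            for m in meta
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------- NPX + LOD


def read_lod(path: str | Path) -> dict[str, float]:
    df = _read_csv(path)
    _require_columns(df, ["protein", "lod"], path)
    _no_duplicates(df["protein"], path, "protein")
    df = _numeric(df, ["lod"], path)
    return {str(p): float(v) for p, v in zip(df.protein, df.lod)}


def write_lod(lod: dict[str, float], path: str | Path) -> None:
    pd.DataFrame({"protein": list(lod), "lod": list(lod.values())}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_npx(path: str | Path, lod_path: str | Path | None = None) -> list[SecretomeProfile]:
    """NPX matrix: sample rows, protein columns, with a companion LOD table.

    Without an LOD table every value is treated as detected (with a
    warning), since censoring cannot be established.
    """
    df = _read_csv(path)
    _require_columns(df, _NPX_FIXED, path)
    _no_duplicates(df["sample_id"], path, "sample_id")
    proteins = [c for c in df.columns if c not in _NPX_FIXED]
    if not proteins:
        raise ParseError(f"{path}: no protein columns found")
    df = _numeric(df, proteins, path)
    if lod_path is not None:
        lod = read_lod(lod_path)
        missing = [p for p in proteins if p not in lod]
        if missing:
            raise ParseError(f"{lod_path}: no LOD for protein(s) {missing[:5]}")
    else:
        warnings.warn(f"{path}: no LOD table supplied; treating all values as detected",
                      stacklevel=2)
        lod = {p: -np.inf for p in proteins}
    profiles = []
    for _, row in df.iterrows():
        npx = {p: float(row[p]) for p in proteins}
        profiles.append(
            SecretomeProfile(
                sample_id=str(row.sample_id),
                source=str(row.source),
                site=str(row.site),
                npx=npx,
                below_lod={p: npx[p] < lod[p] for p in proteins},
                panel=tuple(proteins),
            )
        )
    return profiles


def write_npx(profiles: Sequence[SecretomeProfile], path: str | Path) -> None:
    if not profiles:
        raise ParseError("no profiles to write")
    panel = profiles[0].panel
    rows = []
    for p in profiles:
        row = {"sample_id": p.sample_id, "source": p.source, "site": p.site}
        row.update({prot: p.npx[prot] for prot in panel})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------- expression


def read_expression(path: str | Path, labels_path: str | Path | None = None) -> ExpressionMatrix:
    """Genes x samples CSV, first column the gene identifier."""
    df = _read_csv(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected a gene-id column plus sample columns")
    gene_col = df.columns[0]
    _no_duplicates(df[gene_col], path, "gene id")
    samples = list(df.columns[1:])
    if len(set(samples)) != len(samples):
        raise ParseError(f"{path}: duplicate sample identifiers in header")
    df = _numeric(df, samples, path)
    labels = read_labels(labels_path) if labels_path is not None else {}
    return ExpressionMatrix(
        genes=tuple(str(g) for g in df[gene_col]),
        samples=tuple(samples),
        values=df[samples].to_numpy(dtype=float),
        labels=labels,
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.insert(0, "gene_id", list(matrix.genes))
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_labels(path: str | Path) -> dict[str, str]:
    df = _read_csv(path)
    _require_columns(df, ["sample_id", "label"], path)
    _no_duplicates(df["sample_id"], path, "sample_id")
    return {str(s): str(l) for s, l in zip(df.sample_id, df.label)}


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    pd.DataFrame({"sample_id": list(labels), "label": list(labels.values())}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------- gene sets


def read_gmt(path: str | Path) -> list[SignatureDef]:
    """GMT: one gene set per line — name, description, then member genes."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    sigs = []
    seen = set()
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}: line {i}: GMT lines need >= 3 tab-separated fields")
        name = fields[0]
        if name in seen:
            raise ParseError(f"{path}: line {i}: duplicate gene set {name!r}")
        seen.add(name)
        sigs.append(SignatureDef(name=name, genes=tuple(g for g in fields[2:] if g)))
    return sigs


def write_gmt(sigs: Sequence[SignatureDef], path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([s.name, description, *s.genes])
        for s in sigs
        if not s.composite_of
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_composites(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Two-column TSV mapping composite signature -> component signature."""
    df = _read_csv(path, sep="\t")
    _require_columns(df, ["composite", "component"], path)
    out: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row.composite), []).append(str(row.component))
    return {k: tuple(v) for k, v in out.items()}


def write_composites(composites: dict[str, Sequence[str]], path: str | Path) -> None:
    rows = [
        {"composite": name, "component": comp}
        for name, comps in composites.items()
        for comp in comps
    ]
    pd.DataFrame(rows, columns=["composite", "component"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- results


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Result tables go out as TSV with full float precision."""
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
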