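"""Migration-secretome correlation screen and candidate-chemokine selection.

For each immune subset, absolute migrated-cell counts per TME sample are
correlated (Pearson) against each detected protein's NPX across samples;
p-values receive Benjamini-Hochberg correction within the subset's protein
family. Candidate chemokines for an anchor subset are the significantly
positively correlated proteins that also pass the cell-line-vs-TME presence
contrast (absent from every tumor cell line, present in most tumor media) —
proteins whose secretion plausibly originates in the stroma and drives
dendritic-cell recruitment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .secretome import PresenceContrast, SecretomeProfile, detected_proteins
from .stats import bh_fdr, pearson

__all__ = ["AssociationRecord", "CandidateSelection", "screen", "select_candidates"]


@dataclass(frozen=True)
class AssociationRecord:
    """One (subset, protein) correlation with its BH-adjusted significance."""

    subset: str
    protein: str
    r: float
    p: float
    q: float
    n: int
    significant: bool
    degenerate: bool = False


@dataclass(frozen=True)
class CandidateSelection:
    """Selection outcome for one anchor subset."""

    subset: str
    significant_positive: tuple[str, ...]
    candidates: tuple[str, ...]


def screen(
    migration_counts: pd.DataFrame,
    npx_profiles: Sequence[SecretomeProfile],
    alpha: float = 0.05,
    lod: Mapping[str, float] | None = None,
    fdr_family: str = "per_subset",
    use_corrected: bool = True,
) -> pd.DataFrame:
    """Correlate per-sample migration counts with NPX across the panel.

    Parameters
    ----------
    migration_counts : DataFrame
        Rows indexed by sample_id (matching NPX profile sample ids), one
        column per immune subset, values = mean absolute migrated counts.
    npx_profiles : sequence of SecretomeProfile
        TME secretome profiles; screening is restricted to proteins
        detected in at least one profile.
    alpha : float
        Significance cutoff applied to q (or to raw p when
        ``use_corrected=False``).
    fdr_family : 'per_subset' | 'global'
        Family over which BH correction is applied.
    """
    if fdr_family not in ("per_subset", "global"):
        raise AnalysisError(f"unknown fdr_family {fdr_family!r}")
    tme = [p for p in npx_profiles if p.source == "tme"]
    if not tme:
        raise AnalysisError("screen needs TME profiles")
    by_id = {p.sample_id: p for p in tme}
    shared = [s for s in migration_counts.index if s in by_id]
    if len(shared) < 3:
        raise AnalysisError(
            f"screen needs >= 3 samples shared between migration and NPX; got {len(shared)}"
        )
    proteins = sorted(detected_proteins(tme))
    lod_d = dict(lod) if lod is not None else None

    rows: list[dict] = []
    for subset in migration_counts.columns:
        counts = migration_counts.loc[shared, subset].to_numpy(dtype=float)
        for protein in proteins:
            vals = np.array([by_id[s].value(protein, lod_d) for s in shared])
            res = pearson(counts, vals)
            rows.append(
                {
                    "subset": subset,
                    "protein": protein,
                    "r": res.statistic,
                    "p": res.p_value,
                    "n": len(shared),
                    "degenerate": res.degenerate,
                }
            )
    df = pd.DataFrame(rows)

    # BH within family, degenerate records excluded from the family.
    df["q"] = np.nan
    ok = ~df["degenerate"]
    if fdr_family == "per_subset":
        for subset in migration_counts.columns:
            mask = ok & (df["subset"] == subset)
            if mask.any():
                df.loc[mask, "q"] = bh_fdr(df.loc[mask, "p"].tolist()).q_values
    else:
        if ok.any():
            df.loc[ok, "q"] = bh_fdr(df.loc[ok, "p"].tolist()).q_values
    crit = df["q"] if use_corrected else df["p"]
    df["significant"] = ok & (crit < alpha)
    return df[["subset", "protein", "r", "p", "q", "n", "significant", "degenerate"]]


def select_candidates(
    records: pd.DataFrame,
    contrasts: Sequence[PresenceContrast] | pd.DataFrame,
    anchor_subset: str = "cDC1",
) -> CandidateSelection:
    """Candidate chemokines: significant positive correlates of the anchor
    subset's migration that also pass the presence contrast."""
    if anchor_subset not in set(records["subset"]):
        raise AnalysisError(f"anchor subset {anchor_subset!r} absent from records")
    if isinstance(contrasts, pd.DataFrame):
        passing = set(contrasts.loc[contrasts["passes"].astype(bool), "protein"])
    else:
        passing = {c.protein for c in contrasts if c.passes}
    sub = records[(records["subset"] == anchor_subset) & records["significant"] & (records["r"] > 0)]
    significant_positive = tuple(sorted(sub["protein"]))
    candidates = tuple(sorted(set(significant_positive) & passing))
    return CandidateSelection(anchor_subset, significant_positive, candidates)
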