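"""NPX secretome profiles with limit-of-detection semantics.

Olink-style NPX values are relative, log2-scale protein abundances that are
comparable across samples for one protein but not between proteins. Each
protein carries a limit of detection (LOD); values below it are reported
but flagged as not detected. This module computes detection summaries and
the cell-line-vs-tumor presence contrast used for candidate selection: a
protein that is below LOD in every cell-line secretome yet present in a
strict majority of tumor (TME) secretomes is likely stroma- or
immune-derived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import AnalysisError
from .stats import TestResult, mann_whitney

__all__ = [
    "SecretomeProfile",
    "PresenceContrast",
    "detected_proteins",
    "presence_contrast",
    "group_npx_compare",
]


@dataclass
class SecretomeProfile:
    """One sample's NPX vector with per-protein detection flags."""

    sample_id: str
    source: str  # cell_line | tme
    npx: dict[str, float]
    below_lod: dict[str, bool]
    site: str = "none"
    panel: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.source not in ("cell_line", "tme"):
            raise AnalysisError(f"sample {self.sample_id}: unknown source {self.source!r}")
        if not self.panel:
            self.panel = tuple(self.npx)
        if len(set(self.panel)) != len(self.panel):
            raise AnalysisError(f"sample {self.sample_id}: duplicate proteins in panel")
        if set(self.npx) != set(self.panel) or set(self.below_lod) != set(self.panel):
            raise AnalysisError(
                f"sample {self.sample_id}: npx/below_lod keys do not match the panel"
            )

    def detected(self, protein: str) -> bool:
        self._check(protein)
        return not self.below_lod[protein]

    def value(self, protein: str, lod: dict[str, float] | None = None, floor: str = "lod") -> float:
        """NPX value for analysis; below-LOD values are substituted.

        ``floor='lod'`` replaces censored values by the protein's LOD (the
        standard NPX convention), ``'half_lod'`` by LOD - 1 (half on the
        linear scale), ``'raw'`` keeps the reported value.
        """
        self._check(protein)
        v = self.npx[protein]
        if not self.below_lod[protein] or floor == "raw":
            return v
        if lod is None or protein not in lod:
            return v
        return lod[protein] if floor == "lod" else lod[protein] - 1.0

    def _check(self, protein: str) -> None:
        if protein not in self.npx:
            raise AnalysisError(f"unknown protein {protein!r} for sample {self.sample_id}")


@dataclass(frozen=True)
class PresenceContrast:
    """Cell-line-vs-TME presence contrast for one protein."""

    protein: str
    all_cell_lines_below_lod: bool
    tme_detected_fraction: float
    passes: bool


def _require(profiles: Sequence[SecretomeProfile], what: str) -> None:
    if len(profiles) == 0:
        raise AnalysisError(f"need at least one {what} profile")


def detected_proteins(
    tme_profiles: Sequence[SecretomeProfile], min_detected_samples: int = 1
) -> set[str]:
    """Proteins above LOD in at least ``min_detected_samples`` TME samples."""
    _require(tme_profiles, "TME")
    panel = tme_profiles[0].panel
    out = set()
    for protein in panel:
        n_det = sum(p.detected(protein) for p in tme_profiles)
        if n_det >= min_detected_samples:
            out.add(protein)
    return out


def presence_contrast(
    protein: str,
    cell_line_profiles: Sequence[SecretomeProfile],
    tme_profiles: Sequence[SecretomeProfile],
    majority_threshold: float = 0.5,
) -> PresenceContrast:
    """Stroma-origin contrast: absent from every cell line, present in most tumors.

    Passes iff the protein is below LOD in ALL cell-line profiles and above
    LOD in a strict majority (> ``majority_threshold`` fraction) of TME
    profiles.
    """
    _require(cell_line_profiles, "cell-line")
    _require(tme_profiles, "TME")
    all_below = all(not p.detected(protein) for p in cell_line_profiles)
    frac = sum(p.detected(protein) for p in tme_profiles) / len(tme_profiles)
    return PresenceContrast(
        protein=protein,
        all_cell_lines_below_lod=all_below,
        tme_detected_fraction=frac,
        passes=all_below and frac > majority_threshold,
    )


def group_npx_compare(
    protein: str,
    profiles: Sequence[SecretomeProfile],
    grouping: tuple[str, str],
    lod: dict[str, float] | None = None,
    floor: str = "lod",
) -> TestResult:
    """Two-sided Mann-Whitney on NPX between two anatomical sites.

    Below-LOD values participate at their floored value (the per-protein
    LOD by default) so censored samples still contribute rank information.
    """
    site_a, site_b = grouping
    group_a = [p.value(protein, lod, floor) for p in profiles if p.site == site_a]
    group_b = [p.value(protein, lod, floor) for p in profiles if p.site == site_b]
    if len(group_a) < 2 or len(group_b) < 2:
        raise AnalysisError(
            f"group_npx_compare needs >= 2 samples per site; got "
            f"{len(group_a)} for {site_a!r} and {len(group_b)} for {site_b!r}"
        )
    return mann_whitney(group_a, group_b)
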