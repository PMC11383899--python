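"""Transwell migration quantification and induction calling.

Turns per-well flow-cytometry event counts into absolute migrated-cell
counts via counting beads, applies donor quality control (positive/negative
control ratio), normalizes migration to the positive-control chemokine mix,
and calls migration induction per attractant x immune subset with the
mean + 2 SD rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .stats import TestResult, fisher_exact_2x2, wilcoxon_signed_rank

__all__ = [
    "DEFAULT_SUBSETS",
    "AttractantClass",
    "MigrationWell",
    "AttractantMeta",
    "MigrationCall",
    "beads_to_count",
    "donor_qc",
    "normalize_percent",
    "call_active",
    "summarize_experiment",
    "hpv_contingency",
    "compare_paired",
]

#: Immune subsets of the default flow panel.
DEFAULT_SUBSETS: tuple[str, ...] = (
    "cDC1",
    "cDC2",
    "B_cell",
    "CD4_T",
    "CD8_T",
    "monocyte",
    "pDC",
)


class AttractantClass(str, Enum):
    NEGATIVE_CONTROL = "negative_control"
    POSITIVE_CONTROL = "positive_control"
    CELL_LINE = "cell_line"
    TME_MEDIUM = "tme_medium"


@dataclass
class MigrationWell:
    """One lower-compartment transwell measurement."""

    well_id: str
    attractant_id: str
    attractant_class: AttractantClass
    donor_id: str
    replicate: int
    subset_events: dict[str, int]
    bead_events: int
    beads_added: int

    def __post_init__(self) -> None:
        self.attractant_class = AttractantClass(self.attractant_class)
        if self.replicate < 1:
            raise AnalysisError(f"well {self.well_id}: replicate must be >= 1")
        if self.beads_added < 1:
            raise AnalysisError(f"well {self.well_id}: beads_added must be positive")
        if self.bead_events < 0 or any(v < 0 for v in self.subset_events.values()):
            raise AnalysisError(f"well {self.well_id}: negative event counts")

    def absolute_count(self, subset: str) -> float:
        return beads_to_count(self.subset_events[subset], self.bead_events, self.beads_added)


@dataclass
class AttractantMeta:
    """Attractant annotations: HPV status, anatomical site, fibroblast depletion."""

    attractant_id: str
    hpv_status: str = "not_applicable"  # negative | positive | not_applicable
    site: str = "none"  # OCSCC | LSCC | HSCC | OPSCC_HPVneg | OPSCC_HPVpos | none
    fibroblast_depleted: bool = False


@dataclass
class MigrationCall:
    """Induction call for one attractant x subset."""

    attractant_id: str
    subset: str
    mean_count: float
    normalized_percent: float
    n_replicates: int
    threshold: float
    induced: bool | None  # None when no QC-passing donors remain

    def __post_init__(self) -> None:
        if self.induced is not None and self.n_replicates > 0:
            assert self.induced == (self.mean_count > self.threshold)


def beads_to_count(subset_events: float, bead_events: float, beads_added: float) -> float:
    """Absolute cell count from the cell:bead event ratio.

    A known quantity of counting beads is spiked into each sample, so
    ``count = events * beads_added / bead_events``.
    """
    if bead_events <= 0:
        raise AnalysisError("well is unquantifiable: no bead events acquired")
    return subset_events * beads_added / bead_events


def donor_qc(positive_mean: float, negative_mean: float, ratio_cutoff: float = 2.5) -> bool:
    """Donor inclusion rule: positive/negative control migration ratio.

    A donor is excluded when the ratio of migration toward the positive
    control over the negative control is below ``ratio_cutoff`` (a ratio of
    exactly 2.5 is included). A zero negative control with positive
    migration passes (infinite ratio).
    """
    if positive_mean < 0 or negative_mean < 0:
        raise AnalysisError("control means must be nonnegative")
    if positive_mean == 0 and negative_mean == 0:
        warnings.warn("degenerate donor: both control means zero; excluding", stacklevel=2)
        return False
    if negative_mean == 0:
        return True
    return positive_mean / negative_mean >= ratio_cutoff


def normalize_percent(count: float, positive_mean: float) -> float:
    """Migration as a percentage of the positive-control mean (= 100)."""
    if positive_mean <= 0:
        raise AnalysisError("positive-control mean must be positive for normalization")
    return 100.0 * count / positive_mean


def call_active(
    attractant_counts: Sequence[float],
    negative_counts: Sequence[float],
    sd_multiplier: float = 2.0,
    attractant_id: str = "",
    subset: str = "",
    positive_mean: float | None = None,
) -> MigrationCall:
    """Call migration induction against the negative-control distribution.

    Induced iff mean(attractant) strictly exceeds
    mean(negative) + ``sd_multiplier`` * sample SD(negative).
    """
    att = np.asarray(attractant_counts, dtype=float)
    neg = np.asarray(negative_counts, dtype=float)
    if att.size < 1:
        raise AnalysisError("call_active needs >= 1 attractant replicate")
    if neg.size < 2:
        raise AnalysisError("call_active needs >= 2 negative-control replicates")
    threshold = float(neg.mean() + sd_multiplier * neg.std(ddof=1))
    mean_count = float(att.mean())
    pct = (
        normalize_percent(mean_count, positive_mean)
        if positive_mean is not None
        else math.nan
    )
    return MigrationCall(
        attractant_id=attractant_id,
        subset=subset,
        mean_count=mean_count,
        normalized_percent=pct,
        n_replicates=int(att.size),
        threshold=threshold,
        induced=mean_count > threshold,
    )


def _wells_frame(wells: Iterable[MigrationWell], subsets: Sequence[str]) -> pd.DataFrame:
    rows = []
    for w in wells:
        row = {
            "well_id": w.well_id,
            "attractant_id": w.attractant_id,
            "attractant_class": AttractantClass(w.attractant_class).value,
            "donor_id": w.donor_id,
            "replicate": w.replicate,
        }
        for s in subsets:
            if s in w.subset_events:
                row[s] = w.absolute_count(s)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_experiment(
    wells: Sequence[MigrationWell],
    meta: Sequence[AttractantMeta] | None = None,
    subsets: Sequence[str] = DEFAULT_SUBSETS,
    ratio_cutoff: float = 2.5,
    sd_multiplier: float = 2.0,
    donor_pooling: str = "mean",
) -> pd.DataFrame:
    """Per attractant x subset migration calls from a well table.

    Per donor x subset, donor QC compares the donor's positive- and
    negative-control means; excluded donors are dropped for that subset.
    Induction is called on absolute bead-scaled counts pooled across the
    remaining donors against their pooled negative controls.
    ``normalized_percent`` divides by the same donor's positive-control
    mean before pooling (donors differ systematically in baseline
    migration). ``donor_pooling='separate'`` emits one row per donor
    instead of pooling.
    """
    if donor_pooling not in ("mean", "separate"):
        raise AnalysisError(f"unknown donor_pooling {donor_pooling!r}")
    subsets = [s for s in subsets]
    df = _wells_frame(wells, subsets)
    if df.empty:
        raise AnalysisError("no wells supplied")
    present_subsets = [s for s in subsets if s in df.columns]

    neg = df[df.attractant_class == AttractantClass.NEGATIVE_CONTROL.value]
    pos = df[df.attractant_class == AttractantClass.POSITIVE_CONTROL.value]
    for donor in df.donor_id.unique():
        if neg[neg.donor_id == donor].empty or pos[pos.donor_id == donor].empty:
            raise AnalysisError(f"donor {donor!r} lacks negative- or positive-control wells")

    # Donor QC per donor x subset, on absolute counts.
    included: dict[tuple[str, str], bool] = {}
    pos_means: dict[tuple[str, str], float] = {}
    neg_by_donor: dict[tuple[str, str], np.ndarray] = {}
    for donor in df.donor_id.unique():
        for s in present_subsets:
            p = pos.loc[pos.donor_id == donor, s].dropna().to_numpy()
            n = neg.loc[neg.donor_id == donor, s].dropna().to_numpy()
            if p.size == 0 or n.size == 0:
                included[(donor, s)] = False
                continue
            pos_means[(donor, s)] = float(p.mean())
            neg_by_donor[(donor, s)] = n
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                included[(donor, s)] = donor_qc(float(p.mean()), float(n.mean()), ratio_cutoff)

    records: list[dict] = []
    attractants = df.attractant_id.unique()
    for att_id in attractants:
        att_wells = df[df.attractant_id == att_id]
        att_class = att_wells.attractant_class.iloc[0]
        for s in present_subsets:
            donors = sorted(att_wells.donor_id.unique())
            if donor_pooling == "separate":
                donor_groups = [[d] for d in donors]
            else:
                donor_groups = [donors]
            for group in donor_groups:
                use = [d for d in group if included.get((d, s), False)]
                label = group[0] if donor_pooling == "separate" else None
                counts = att_wells.loc[att_wells.donor_id.isin(use), s].dropna().to_numpy()
                neg_counts = (
                    np.concatenate([neg_by_donor[(d, s)] for d in use]) if use else np.array([])
                )
                rec = {"attractant_id": att_id, "attractant_class": att_class, "subset": s}
                if donor_pooling == "separate":
                    rec["donor_id"] = label
                if counts.size == 0 or neg_counts.size < 2:
                    rec.update(
                        mean_count=math.nan,
                        normalized_percent=math.nan,
                        threshold=math.nan,
                        induced=pd.NA,
                        n_replicates=0,
                    )
                    records.append(rec)
                    continue
                call = call_active(counts, neg_counts, sd_multiplier, att_id, s)
                pct = float(
                    np.mean(
                        [
                            normalize_percent(
                                att_wells.loc[att_wells.donor_id == d, s].dropna().mean(),
                                pos_means[(d, s)],
                            )
                            for d in use
                        ]
                    )
                )
                rec.update(
                    mean_count=call.mean_count,
                    normalized_percent=pct,
                    threshold=call.threshold,
                    induced=call.induced,
                    n_replicates=call.n_replicates,
                )
                records.append(rec)
    out = pd.DataFrame(records)
    out["induced"] = out["induced"].astype("boolean")
    if meta is not None:
        meta_df = pd.DataFrame(
            [
                {
                    "attractant_id": m.attractant_id,
                    "hpv_status": m.hpv_status,
                    "site": m.site,
                    "fibroblast_depleted": m.fibroblast_depleted,
                }
                for m in meta
            ]
        )
        out = out.merge(meta_df, on="attractant_id", how="left")
    return out


def mean_absolute_counts(
    wells: Sequence[MigrationWell],
    subsets: Sequence[str] = DEFAULT_SUBSETS,
    attractant_class: AttractantClass | str | None = AttractantClass.TME_MEDIUM,
) -> pd.DataFrame:
    """Mean absolute migrated count per attractant x subset.

    Bead-scaled counts averaged over all replicates and donors; the
    per-sample migration quantity the correlation screen consumes.
    """
    df = _wells_frame(wells, list(subsets))
    if attractant_class is not None:
        cls = AttractantClass(attractant_class).value
        df = df[df.attractant_class == cls]
    if df.empty:
        raise AnalysisError("no wells of the requested attractant class")
    cols = [s for s in subsets if s in df.columns]
    return df.groupby("attractant_id")[cols].mean()


def hpv_contingency(
    calls: pd.DataFrame, subset: str
) -> tuple[pd.DataFrame, TestResult]:
    """2x2 HPV-status x induction contingency over cell-line attractants.

    Rows are HPV status (negative, positive), columns induced yes/no;
    the p-value comes from the two-sided Fisher exact test.
    """
    if "hpv_status" not in calls.columns:
        raise AnalysisError("calls lack hpv_status; pass attractant metadata")
    sub = calls[(calls["subset"] == subset)]
    if "attractant_class" in sub.columns:
        sub = sub[sub["attractant_class"] == AttractantClass.CELL_LINE.value]
    if sub.empty:
        raise AnalysisError(f"no cell-line calls for subset {subset!r}")
    if sub["hpv_status"].isna().any() or (~sub["hpv_status"].isin(["negative", "positive"])).any():
        raise AnalysisError("every cell line needs an HPV status of negative or positive")
    if sub["induced"].isna().any():
        raise AnalysisError("cannot build contingency from missing induction calls")
    tab = pd.DataFrame(
        {
            "induced": [
                int(((sub.hpv_status == "negative") & sub.induced.astype(bool)).sum()),
                int(((sub.hpv_status == "positive") & sub.induced.astype(bool)).sum()),
            ],
            "not_induced": [
                int(((sub.hpv_status == "negative") & ~sub.induced.astype(bool)).sum()),
                int(((sub.hpv_status == "positive") & ~sub.induced.astype(bool)).sum()),
            ],
        },
        index=pd.Index(["negative", "positive"], name="hpv_status"),
    )
    result = fisher_exact_2x2(
        tab.loc["negative", "induced"],
        tab.loc["negative", "not_induced"],
        tab.loc["positive", "induced"],
        tab.loc["positive", "not_induced"],
    )
    return tab, result


def compare_paired(
    calls_total: Mapping[str, float],
    calls_depleted: Mapping[str, float],
    subset: str = "",
) -> TestResult:
    """Paired comparison of normalized migration between two arms.

    Typical use: total TME-conditioned medium vs fibroblast-depleted medium
    from the same tumor specimens. Two-sided Wilcoxon signed-rank on the
    per-specimen normalized percents.
    """
    keys_a, keys_b = set(calls_total), set(calls_depleted)
    if keys_a != keys_b:
        raise AnalysisError(
            f"unmatched sample sets: {sorted(keys_a ^ keys_b)} present in only one arm"
        )
    order = sorted(keys_a)
    a = [calls_total[k] for k in order]
    b = [calls_depleted[k] for k in order]
    return wilcoxon_signed_rank(a, b)
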