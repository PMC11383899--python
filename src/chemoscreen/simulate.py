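"""Synthetic study generator with recorded ground truth.

Emulates the three data layers of a secretome-and-migration study so every
pipeline stage is testable end to end:

* **Secretome** — a 92-protein NPX panel measured on tumor cell-line and
  TME-conditioned media. Four planted chemokines are secreted only by the
  stromal compartment: absent (below LOD) in all cell lines, present in
  most TME media, and co-varying through a shared stromal-activity factor
  (in the motivating biology they are co-secreted by cancer-associated
  fibroblasts).
* **Migration** — transwell well tables with counting beads. Migrated
  counts are negative binomial; the mean for dendritic subsets scales with
  the sample's latent chemokine secretion, T-cell weights are zero (no
  T-cell chemotaxis toward tumor media), and multiplicative per-donor
  effects reproduce PBMC donor variability.
* **Expression** — a small immunotherapy cohort (3 responders vs 13
  non-responders) with +1 SD shifts planted in designated gene signatures.

All outputs are pure functions of ``(config, seed)``; sub-generators draw
from independent streams spawned as ``default_rng([seed, stream])`` so
regenerating one layer never perturbs another.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm

from .errors import AnalysisError
from .migration import DEFAULT_SUBSETS, AttractantMeta, MigrationWell
from .secretome import SecretomeProfile
from .signatures import ExpressionMatrix, SignatureDef

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_secretome",
    "simulate_migration",
    "simulate_expression",
    "simulate_all",
    "null_config",
]

_SITES = ("OCSCC", "LSCC", "HSCC", "OPSCC_HPVneg", "OPSCC_HPVpos")

# Streams for seed splitting (default_rng([seed, stream])).
_STREAM_SECRETOME = 1
_STREAM_MIGRATION = 2
_STREAM_EXPRESSION = 3


def _default_baselines() -> dict[str, float]:
    # Spontaneous migration toward medium only, in cells per well.
    return {
        "cDC1": 40.0,
        "cDC2": 150.0,
        "B_cell": 300.0,
        "CD4_T": 500.0,
        "CD8_T": 400.0,
        "monocyte": 200.0,
        "pDC": 30.0,
    }


def _default_weights() -> dict[str, float]:
    # Responsiveness of each subset to the planted stromal chemokines.
    # T-cell weights are zero: tumor-conditioned media do not attract
    # T cells, the study's central negative finding.
    return {
        "cDC1": 1.0,
        "cDC2": 1.0,
        "B_cell": 0.5,
        "CD4_T": 0.0,
        "CD8_T": 0.0,
        "monocyte": 0.3,
        "pDC": 0.0,
    }


def _default_site_shift() -> dict[str, float]:
    # log2 shift of stromal activity by anatomical site: laryngeal media
    # carry a sparser secretome, hypopharyngeal a richer one.
    return {"OCSCC": 0.0, "LSCC": -0.5, "HSCC": 0.5, "OPSCC_HPVneg": 0.0, "OPSCC_HPVpos": 0.0}


@dataclass
class SimulationConfig:
    """Study design and effect sizes for the synthetic cohort.

    Defaults mirror the motivating study: 28 TME-conditioned media, 11
    tumor cell lines (3 HPV-positive), two PBMC donors with two replicate
    wells each, a 92-protein panel with 4 planted stroma-only chemokines,
    and an expression cohort of 16 patients (3 MPR, 13 NPR).
    """

    seed: int = 0
    # secretome design
    n_tme_samples: int = 28
    n_cell_lines: int = 11
    n_hpv_positive: int = 3
    panel_size: int = 92
    planted_chemokines: tuple[str, ...] = ("CCL7", "CCL8", "CCL13", "CXCL5")
    npx_noise_sd: float = 0.3
    lod_quantile: float = 0.9999
    stromal_level: float = 4.0  # log2 NPX units above background for planted proteins in TME
    stromal_common_sd: float = 0.8  # shared stromal-activity factor (log2)
    stromal_protein_sd: float = 0.4  # per-protein deviation around the common factor (log2)
    shared_sample_sd: float = 0.8  # per-sample variation of ubiquitous proteins (log2)
    tme_boost_max: float = 2.0  # ubiquitous proteins run higher in TME media (log2)
    absent_fraction: float = 0.3  # fraction of background panel below LOD everywhere
    site_stromal_shift: dict[str, float] = field(default_factory=_default_site_shift)
    # migration design
    n_donors: int = 2
    n_replicates: int = 2
    subsets: tuple[str, ...] = DEFAULT_SUBSETS
    baseline_negative_mean: dict[str, float] = field(default_factory=_default_baselines)
    responsiveness: dict[str, float] = field(default_factory=_default_weights)
    positive_control_multiplier: float = 6.0
    chemokine_gain: float = 4.0  # migration multiplier per unit relative secretion
    cell_line_cdc2_level: float = 5.0  # typical cDC2 attraction of HPV-negative lines
    cell_line_effect_sd: float = 0.5  # lognormal spread of cell-line attraction
    count_dispersion: float = 10.0  # NB size parameter; variance = mu + mu^2/size
    donor_effect_sd: float = 0.3  # lognormal sigma per donor x subset
    beads_added: int = 20000
    # expression design
    n_genes: int = 2000
    n_expr_samples: int = 16
    n_mpr: int = 3
    genes_per_signature: int = 25
    signature_shift_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.lod_quantile < 1.0:
            raise AnalysisError("lod_quantile must lie in (0, 1)")
        if self.n_hpv_positive > self.n_cell_lines:
            raise AnalysisError("n_hpv_positive exceeds n_cell_lines")
        if len(self.planted_chemokines) > self.panel_size:
            raise AnalysisError("planted chemokines exceed panel size")
        if self.n_expr_samples < 4:
            raise AnalysisError("expression cohort needs >= 4 samples")
        if self.n_mpr >= self.n_expr_samples:
            raise AnalysisError("n_mpr must leave at least one non-responder")
        for name, v in (
            ("positive_control_multiplier", self.positive_control_multiplier),
            ("count_dispersion", self.count_dispersion),
        ):
            if v <= 0:
                raise AnalysisError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """Latent state recorded by the generators."""

    planted_chemokines: tuple[str, ...] = ()
    panel: tuple[str, ...] = ()
    lod: dict[str, float] = field(default_factory=dict)
    #: linear relative secretion per TME sample x planted protein (median ~1)
    secretion: pd.DataFrame | None = None
    #: per-sample stromal drive (linear), indexed by TME sample id
    stromal_drive: pd.Series | None = None
    #: migration multiplier per attractant x subset
    migration_multiplier: pd.DataFrame | None = None
    sites: dict[str, str] = field(default_factory=dict)
    #: signature name -> gene tuple
    signatures: dict[str, tuple[str, ...]] = field(default_factory=dict)
    composites: dict[str, tuple[str, ...]] = field(default_factory=dict)
    shifted_signatures: tuple[str, ...] = ()
    flat_signatures: tuple[str, ...] = ()
    mpr_samples: tuple[str, ...] = ()

    def to_jsonable(self) -> dict:
        out: dict = {
            "planted_chemokines": list(self.planted_chemokines),
            "panel": list(self.panel),
            "lod": self.lod,
            "sites": self.sites,
            "signatures": {k: list(v) for k, v in self.signatures.items()},
            "composites": {k: list(v) for k, v in self.composites.items()},
            "shifted_signatures": list(self.shifted_signatures),
            "flat_signatures": list(self.flat_signatures),
            "mpr_samples": list(self.mpr_samples),
        }
        if self.secretion is not None:
            out["secretion"] = {
                s: dict(zip(self.secretion.columns, row))
                for s, row in zip(self.secretion.index, self.secretion.to_numpy())
            }
        if self.migration_multiplier is not None:
            out["migration_multiplier"] = {
                s: dict(zip(self.migration_multiplier.columns, row))
                for s, row in zip(
                    self.migration_multiplier.index, self.migration_multiplier.to_numpy()
                )
            }
        return out


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A configuration with every planted effect switched off.

    Used for type-I-error checks: no stromal chemokine secretion, no
    cell-line attraction, no site shifts, no signature shifts. Controls
    (positive-control attraction, donor effects, count dispersion) keep
    their defaults so the null data still look like real assay output.
    """
    cfg = SimulationConfig(
        seed=seed,
        stromal_level=0.0,
        chemokine_gain=0.0,
        cell_line_cdc2_level=1.0,
        cell_line_effect_sd=0.0,
        site_stromal_shift={s: 0.0 for s in _SITES},
        signature_shift_sd=0.0,
        **overrides,
    )
    return cfg


def _panel(config: SimulationConfig) -> tuple[str, ...]:
    n_bg = config.panel_size - len(config.planted_chemokines)
    background = tuple(f"PROT{i + 1:03d}" for i in range(n_bg))
    return tuple(config.planted_chemokines) + background


def _tme_ids(config: SimulationConfig) -> list[str]:
    return [f"T{i + 1:02d}" for i in range(config.n_tme_samples)]


def _cell_line_ids(config: SimulationConfig) -> list[str]:
    return [f"CL{i + 1:02d}" for i in range(config.n_cell_lines)]


def simulate_secretome(config: SimulationConfig) -> tuple[list[SecretomeProfile], GroundTruth]:
    """Generate NPX profiles for cell-line and TME media plus ground truth.

    Background proteins split into an "absent" class (at assay background
    everywhere, hence below LOD) and a "ubiquitous" class (well above LOD
    in both sources, running somewhat higher in TME media). Planted
    chemokines sit at background in cell lines and ``stromal_level`` above
    it in TME media, modulated by a shared per-sample stromal factor, a
    site shift and a per-protein deviation. The per-protein LOD is the
    ``lod_quantile`` upper quantile of the assay background-noise
    distribution (background + z_q * noise SD), an assay property rather
    than a statistic of the simulated samples.
    """
    rng = np.random.default_rng([config.seed, _STREAM_SECRETOME])
    panel = _panel(config)
    planted = set(config.planted_chemokines)
    n_planted = len(config.planted_chemokines)
    tme_ids, cl_ids = _tme_ids(config), _cell_line_ids(config)
    sites = {s: _SITES[i % len(_SITES)] for i, s in enumerate(tme_ids)}

    floor = {p: float(rng.uniform(-1.0, 1.0)) for p in panel}
    z_q = float(_norm.ppf(config.lod_quantile))
    lod = {p: floor[p] + z_q * config.npx_noise_sd for p in panel}

    background = [p for p in panel if p not in planted]
    n_absent = int(round(config.absent_fraction * len(background)))
    absent = set(rng.choice(background, size=n_absent, replace=False)) if n_absent else set()
    shared_mu = {p: float(rng.uniform(2.0, 8.0)) for p in background if p not in absent}
    tme_boost = {p: float(rng.uniform(0.0, config.tme_boost_max)) for p in shared_mu}

    # Stromal latent state for TME samples.
    common = rng.normal(0.0, config.stromal_common_sd, size=len(tme_ids))
    site_shift = np.array([config.site_stromal_shift.get(sites[s], 0.0) for s in tme_ids])
    dev = rng.normal(0.0, config.stromal_protein_sd, size=(len(tme_ids), n_planted))
    log_secretion = common[:, None] + site_shift[:, None] + dev  # log2, median 0
    secretion = pd.DataFrame(
        np.exp2(log_secretion), index=tme_ids, columns=list(config.planted_chemokines)
    )
    stromal_drive = pd.Series(np.exp2(common + site_shift), index=tme_ids)

    profiles: list[SecretomeProfile] = []
    for src, ids in (("cell_line", cl_ids), ("tme", tme_ids)):
        for idx, sid in enumerate(ids):
            npx: dict[str, float] = {}
            for p in panel:
                mu = floor[p]
                if p in planted:
                    if src == "tme":
                        j = list(config.planted_chemokines).index(p)
                        mu = floor[p] + config.stromal_level + log_secretion[idx, j]
                elif p in shared_mu:
                    mu = shared_mu[p] + (tme_boost[p] if src == "tme" else 0.0)
                    mu += float(rng.normal(0.0, config.shared_sample_sd))
                npx[p] = mu + float(rng.normal(0.0, config.npx_noise_sd))
            below = {p: npx[p] < lod[p] for p in panel}
            profiles.append(
                SecretomeProfile(
                    sample_id=sid,
                    source=src,
                    npx=npx,
                    below_lod=below,
                    site=sites.get(sid, "none"),
                    panel=panel,
                )
            )

    truth = GroundTruth(
        planted_chemokines=tuple(config.planted_chemokines),
        panel=panel,
        lod=lod,
        secretion=secretion,
        stromal_drive=stromal_drive,
        sites=sites,
    )
    return profiles, truth


def simulate_migration(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[list[MigrationWell], list[AttractantMeta]]:
    """Generate transwell well tables consistent with the secretome truth.

    The expected migrated count of subset *k* toward attractant *a* for
    donor *d* is ``baseline_k * donor_effect_dk * multiplier_ak``, where the
    multiplier is 1 for the negative control, the positive-control
    multiplier for the chemokine mix, ``1 + gain * w_k * drive_j`` for TME
    media, and an HPV-dependent cDC2 attraction for cell lines. Counts are
    negative binomial; each well's bead acquisition fraction is drawn so
    counting-bead arithmetic inverts the true count within sampling noise.
    """
    if truth.stromal_drive is None:
        raise AnalysisError("simulate_migration needs secretome ground truth")
    rng = np.random.default_rng([config.seed, _STREAM_MIGRATION])
    subsets = list(config.subsets)
    tme_ids, cl_ids = _tme_ids(config), _cell_line_ids(config)
    hpv_positive = set(cl_ids[-config.n_hpv_positive :]) if config.n_hpv_positive else set()

    # Attractant multipliers per subset.
    mult = pd.DataFrame(1.0, index=["NEG", "POS", *cl_ids, *tme_ids], columns=subsets)
    mult.loc["POS", :] = config.positive_control_multiplier
    for cl in cl_ids:
        if cl not in hpv_positive and config.cell_line_cdc2_level > 1.0:
            level = config.cell_line_cdc2_level * float(
                rng.lognormal(0.0, config.cell_line_effect_sd)
            )
            mult.loc[cl, "cDC2"] = max(level, 1.0)
    for t in tme_ids:
        drive = float(truth.stromal_drive[t])
        for k in subsets:
            w = config.responsiveness.get(k, 0.0)
            mult.loc[t, k] = 1.0 + config.chemokine_gain * w * drive
    truth.migration_multiplier = mult

    donors = [f"D{d + 1:02d}" for d in range(config.n_donors)]
    donor_effect = {
        (d, k): float(rng.lognormal(0.0, config.donor_effect_sd))
        for d in donors
        for k in subsets
    }

    wells: list[MigrationWell] = []
    size = config.count_dispersion
    for att in mult.index:
        for d in donors:
            for rep in range(1, config.n_replicates + 1):
                frac = float(rng.uniform(0.3, 0.9))
                bead_events = max(1, int(round(config.beads_added * frac)))
                events: dict[str, int] = {}
                for k in subsets:
                    mu = config.baseline_negative_mean[k] * donor_effect[(d, k)] * mult.loc[att, k]
                    true_count = int(rng.negative_binomial(size, size / (size + mu)))
                    events[k] = int(rng.binomial(true_count, frac))
                cls = {
                    "NEG": "negative_control",
                    "POS": "positive_control",
                }.get(att, "cell_line" if att in cl_ids else "tme_medium")
                wells.append(
                    MigrationWell(
                        well_id=f"{att}_{d}_r{rep}",
                        attractant_id=att,
                        attractant_class=cls,
                        donor_id=d,
                        replicate=rep,
                        subset_events=events,
                        bead_events=bead_events,
                        beads_added=config.beads_added,
                    )
                )

    meta = [
        AttractantMeta("NEG", "not_applicable", "none", False),
        AttractantMeta("POS", "not_applicable", "none", False),
    ]
    for cl in cl_ids:
        meta.append(
            AttractantMeta(cl, "positive" if cl in hpv_positive else "negative", "none", False)
        )
    for t in tme_ids:
        site = truth.sites.get(t, "none")
        hpv = {"OPSCC_HPVpos": "positive", "OPSCC_HPVneg": "negative"}.get(site, "not_applicable")
        meta.append(AttractantMeta(t, hpv, site, False))
    return wells, meta


_SIGNATURE_NAMES = (
    "chemokine",
    "general_DC",
    "cDC1_specific",
    "cDC2_specific",
    "myCAF",
    "iCAF",
    "eCAF",
    "pericyte",
)
_SHIFTED = ("chemokine", "general_DC", "cDC1_specific", "cDC2_specific", "myCAF", "iCAF")
_FLAT = ("eCAF", "pericyte")
_COMPOSITES = {
    "cDC1": ("general_DC", "cDC1_specific"),
    "cDC2": ("general_DC", "cDC2_specific"),
    "DC": ("cDC1", "cDC2"),
}


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, dict[str, str], GroundTruth]:
    """Generate an expression cohort with planted signature shifts.

    Per-gene Gaussian expression (SD 1); responder (MPR) samples receive
    ``signature_shift_sd`` SD added to every gene of the designated "up"
    signatures (chemokine, DC and the myCAF/iCAF fibroblast programs);
    the eCAF and pericyte signatures stay flat.
    """
    rng = np.random.default_rng([config.seed, _STREAM_EXPRESSION])
    n_sig_genes = config.genes_per_signature * len(_SIGNATURE_NAMES)
    if config.n_genes < n_sig_genes:
        raise AnalysisError("n_genes too small for the signature layout")
    genes = tuple(f"G{i + 1:05d}" for i in range(config.n_genes))
    samples = tuple(f"S{i + 1:02d}" for i in range(config.n_expr_samples))

    assignment = rng.permutation(config.n_genes)
    signatures: dict[str, tuple[str, ...]] = {}
    for i, name in enumerate(_SIGNATURE_NAMES):
        idx = assignment[i * config.genes_per_signature : (i + 1) * config.genes_per_signature]
        signatures[name] = tuple(genes[j] for j in sorted(idx))

    mpr = tuple(sorted(rng.choice(samples, size=config.n_mpr, replace=False)))
    labels = {s: ("MPR" if s in mpr else "NPR") for s in samples}

    base = rng.normal(5.0, 2.0, size=config.n_genes)
    values = base[:, None] + rng.normal(0.0, 1.0, size=(config.n_genes, config.n_expr_samples))
    if config.signature_shift_sd:
        mpr_cols = [samples.index(s) for s in mpr]
        gene_pos = {g: i for i, g in enumerate(genes)}
        for name in _SHIFTED:
            rows = [gene_pos[g] for g in signatures[name]]
            values[np.ix_(rows, mpr_cols)] += config.signature_shift_sd

    matrix = ExpressionMatrix(genes=genes, samples=samples, values=values, labels=dict(labels))
    truth = GroundTruth(
        signatures=signatures,
        composites=dict(_COMPOSITES),
        shifted_signatures=_SHIFTED if config.signature_shift_sd else (),
        flat_signatures=_FLAT if config.signature_shift_sd else _SIGNATURE_NAMES,
        mpr_samples=mpr,
    )
    return matrix, labels, truth


def signature_defs(truth: GroundTruth) -> list[SignatureDef]:
    """Signature definitions (atomic + composites) from expression truth."""
    defs = [SignatureDef(name, genes) for name, genes in truth.signatures.items()]
    defs += [SignatureDef(name, (), comps) for name, comps in truth.composites.items()]
    return defs


def simulate_all(config: SimulationConfig):
    """Generate every layer; returns (profiles, wells, meta, matrix, labels, truth)."""
    profiles, truth = simulate_secretome(config)
    wells, meta = simulate_migration(config, truth)
    matrix, labels, expr_truth = simulate_expression(config)
    truth.signatures = expr_truth.signatures
    truth.composites = expr_truth.composites
    truth.shifted_signatures = expr_truth.shifted_signatures
    truth.flat_signatures = expr_truth.flat_signatures
    truth.mpr_samples = expr_truth.mpr_samples
    return profiles, wells, meta, matrix, labels, truth
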