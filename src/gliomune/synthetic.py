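"""Synthetic paired expression / imaging / survival cohorts.

The generator emulates the statistical structure the analysis assumes, so the
whole pipeline is testable without access to clinical data:

* a marker panel of 29 immune cell types totalling 803 disjoint synthetic
  marker genes, nine of them carrying the roles the composite
  pro-/antitumor scores need, plus six pathway gene sets drawn from the
  background genes;
* three infiltration archetypes — C2 "cold" (mean archetype infiltration
  ~0.15), C1 intermediate (~0.45) and C3 inflamed (~0.8, with protumor cell
  types boosted) — expressed as log2-scale shifts on the marker genes of a
  log-normal FPKM baseline;
* subtype-linked pathway activity: hypoxia, angiogenesis, ECM remodeling,
  antigen presentation and leukocyte adhesion up in C3, calcium signaling up
  in the cold subtype (and partly in C1);
* per-sample 4-channel volumes containing an ellipsoidal tumor whose mean
  intensity, rim contrast, texture correlation length and eccentricity depend
  on subtype, with per-batch multiplicative gain / additive offset scanner
  effects and rater-perturbed masks for repeatability testing;
* exponential survival with subtype-specific hazards (cold longest, inflamed
  shortest) and uniform censoring.

All draws derive from a single seed; identical configs produce bit-identical
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import (
    GeneSetCollection,
    read_clinical,
    read_expression,
    read_gmt,
    read_volume_mask,
    write_clinical,
    write_expression,
    write_gmt,
    write_volume,
)
from .scoring import ANTITUMOR_ROLES, PROTUMOR_ROLES

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "CELL_TYPE_NAMES",
    "PATHWAY_NAMES",
    "make_panel",
    "make_pathways",
    "simulate_expression",
    "simulate_images",
    "simulate_survival",
    "make_cohort",
    "save_cohort",
    "load_cohort",
]

SUBTYPES = ("C1", "C2", "C3")

#: the 29 scored cell types; the first nine carry the composite-score roles
CELL_TYPE_NAMES = (
    *PROTUMOR_ROLES,
    *ANTITUMOR_ROLES,
    "Microglia",
    "Monocyte",
    "Macrophage M0",
    "Mast cell",
    "Activated dendritic cell",
    "Plasmacytoid dendritic cell",
    "Immature dendritic cell",
    "Memory B cell",
    "Immature B cell",
    "T helper 1 cell",
    "T helper 2 cell",
    "T helper 17 cell",
    "T follicular helper cell",
    "Gamma delta T cell",
    "Central memory CD4 T cell",
    "Effector memory CD4 T cell",
    "Central memory CD8 T cell",
    "Effector memory CD8 T cell",
    "Natural killer T cell",
    "Eosinophil",
)

PATHWAY_NAMES = (
    "hypoxia",
    "angiogenesis",
    "ecm_remodeling",
    "antigen_presentation",
    "leukocyte_adhesion",
    "calcium_signaling",
)
_C3_UP = PATHWAY_NAMES[:5]

#: archetype infiltration means per subtype (Beta-distributed, bounded)
_INFILTRATION_MEAN = {"C1": 0.45, "C2": 0.15, "C3": 0.8}
_INFILTRATION_CONCENTRATION = 60.0  # keeps the three archetype levels distinct
_PROTUMOR_C3_BOOST = 0.15
# the intermediate subtype is a lymphocyte-active transition state: its
# antitumor compartment is skewed up relative to its overall infiltration,
# which separates it from the plain low<->high infiltration axis
_ANTITUMOR_C1_BOOST = 0.12

#: pathway activity by subtype: C3-up pathways vs the calcium (cold) axis
_PATHWAY_ACTIVITY = {
    "C3_up": {"C1": 0.5, "C2": 0.0, "C3": 1.0},
    "calcium": {"C1": 0.7, "C2": 1.0, "C3": 0.0},
}

# image model: per-subtype tumor appearance (intensity units / voxels)
_TUMOR_CONTRAST = {"C1": 35.0, "C2": 20.0, "C3": 55.0}
_RIM_CONTRAST = {"C1": 12.0, "C2": 5.0, "C3": 25.0}
_TEXTURE_SIGMA = {"C1": 1.2, "C2": 2.0, "C3": 0.7}
_TEXTURE_AMPLITUDE = 12.0
_ECCENTRICITY = {"C1": (0.75, 1.15), "C2": (0.9, 1.1), "C3": (0.55, 0.85)}
_CHANNEL_BACKGROUND = {"T1": 60.0, "T2": 80.0, "FLAIR": 70.0, "T1c": 65.0}
_CHANNEL_CONTRAST_SCALE = {"T1": 0.8, "T2": 1.0, "FLAIR": 1.1, "T1c": 1.3}
_NOISE_SD = 3.0


@dataclass(frozen=True)
class CohortConfig:
    """Every knob of the generator; the defaults are the study conditions.

    Subtype proportions and survival hazards mirror the discovery cohort the
    pipeline is designed around (94/55/61 of 210 samples; mean OS of roughly
    35/46/26 months for C1/C2/C3).
    """

    n_samples: int = 150
    subtype_proportions: tuple[float, float, float] = (94 / 210, 55 / 210, 61 / 210)
    n_cell_types: int = 29
    markers_per_type: int | None = None  # None: split total_marker_genes evenly
    total_marker_genes: int = 803
    n_background_genes: int = 1200
    pathway_size: int = 30
    infiltration_effect: float = 3.0  # log2-units per unit infiltration
    pathway_effect: float = 1.5  # log2-units
    expression_noise_sd: float = 0.5  # log2-units
    image_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_batches: int = 3
    batch_gain_sd: float = 0.1
    batch_offset_sd: float = 5.0
    rater_perturb_radius: int = 1
    hazard_per_subtype: tuple[float, float, float] = (
        1 / 35.3,
        1 / 45.6,
        1 / 25.7,
    )  # C1, C2, C3, in 1/months
    censor_rate: float = 0.2
    label_noise: float = 0.0
    with_images: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise ValueError("subtype_proportions must sum to 1")
        for name in (
            "n_samples",
            "n_cell_types",
            "total_marker_genes",
            "n_background_genes",
            "pathway_size",
            "n_batches",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.markers_per_type is not None and self.markers_per_type <= 0:
            raise ValueError("markers_per_type must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")
        if any(h <= 0 for h in self.hazard_per_subtype):
            raise ValueError("hazards must be positive")
        if self.rater_perturb_radius < 0:
            raise ValueError("rater_perturb_radius must be >= 0")

    def marker_set_sizes(self) -> list[int]:
        if self.markers_per_type is not None:
            return [self.markers_per_type] * self.n_cell_types
        base, rem = divmod(self.total_marker_genes, self.n_cell_types)
        return [base + 1 if i < rem else base for i in range(self.n_cell_types)]


@dataclass
class SyntheticCohort:
    """A fully aligned synthetic cohort (expression, imaging, survival)."""

    config: CohortConfig
    sample_ids: list[str]
    expression: pd.DataFrame  # genes x samples, FPKM
    panel: GeneSetCollection
    pathways: GeneSetCollection
    role_map: dict[str, str]
    true_subtype: pd.Series
    infiltration: pd.DataFrame  # cell types x samples, true archetype levels
    batch: pd.Series
    clinical: pd.DataFrame
    volumes: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    masks_rater2: dict[str, np.ndarray] = field(default_factory=dict)
    masks_intra2: dict[str, np.ndarray] = field(default_factory=dict)


def _cell_type_names(n: int) -> list[str]:
    if n <= len(CELL_TYPE_NAMES):
        return list(CELL_TYPE_NAMES[:n])
    extra = [f"Cell type {i + 1}" for i in range(n - len(CELL_TYPE_NAMES))]
    return list(CELL_TYPE_NAMES) + extra


def make_panel(config: CohortConfig) -> tuple[GeneSetCollection, list[str]]:
    """Disjoint marker sets with stable synthetic gene ids, plus the universe.

    Marker genes are named ``MK_<set>_<i>``, background genes ``BG_<i>``;
    the universe is their concatenation.
    """
    sizes = config.marker_set_sizes()
    names = _cell_type_names(config.n_cell_types)
    sets: dict[str, frozenset[str]] = {}
    roles: dict[str, str] = {}
    universe: list[str] = []
    for t, (name, size) in enumerate(zip(names, sizes)):
        genes = [f"MK_{t:02d}_{i:03d}" for i in range(size)]
        sets[name] = frozenset(genes)
        universe.extend(genes)
        if name in PROTUMOR_ROLES or name in ANTITUMOR_ROLES:
            roles[name] = name  # role == canonical cell-type name
        else:
            roles[name] = "other"
    universe.extend(f"BG_{i:04d}" for i in range(config.n_background_genes))
    panel = GeneSetCollection(sets=sets, roles=roles)
    # disjointness is by construction; assert the invariant anyway
    if sum(len(s) for s in panel.sets.values()) != len(panel.universe()):
        raise AssertionError("marker sets overlap")
    return panel, universe


def make_pathways(config: CohortConfig) -> GeneSetCollection:
    """Six pathway sets carved from the background genes (disjoint)."""
    needed = len(PATHWAY_NAMES) * config.pathway_size
    if needed > config.n_background_genes:
        raise ValueError(
            f"need {needed} background genes for pathways, "
            f"have {config.n_background_genes}"
        )
    sets = {}
    for k, name in enumerate(PATHWAY_NAMES):
        start = k * config.pathway_size
        sets[name] = frozenset(
            f"BG_{i:04d}" for i in range(start, start + config.pathway_size)
        )
    return GeneSetCollection(sets=sets, roles={n: "pathway" for n in PATHWAY_NAMES})


def _draw_labels(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    labels = rng.choice(SUBTYPES, size=config.n_samples, p=config.subtype_proportions)
    if config.n_samples >= 30:
        # re-draw on the (vanishingly rare) event a subtype is absent
        attempts = 0
        while len(set(labels)) < 3 and attempts < 100:
            labels = rng.choice(
                SUBTYPES, size=config.n_samples, p=config.subtype_proportions
            )
            attempts += 1
    return labels


def simulate_expression(
    panel: GeneSetCollection,
    pathways: GeneSetCollection,
    labels: np.ndarray | pd.Series,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    universe: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FPKM matrix with archetype infiltration and pathway structure.

    Returns ``(expression, infiltration)``: the genes x samples FPKM matrix
    and the true cell-type x samples archetype infiltration used to build it
    (the ground truth the scoring stage should recover).
    """
    labels = np.asarray(labels)
    unknown = set(labels) - set(SUBTYPES)
    if unknown:
        raise ValueError(f"unknown subtype labels: {sorted(unknown)}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if universe is None:
        _, universe = make_panel(config)
    n = len(labels)
    genes = list(universe)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    baseline = rng.normal(5.0, 2.0, size=n_genes).clip(min=0.5)
    log2x = baseline[:, None] + rng.normal(
        0.0, config.expression_noise_sd, size=(n_genes, n)
    )

    # archetype infiltration per sample, per cell type
    base = np.empty(n)
    for st in SUBTYPES:
        sel = labels == st
        m = _INFILTRATION_MEAN[st]
        nu = _INFILTRATION_CONCENTRATION
        base[sel] = rng.beta(m * nu, (1 - m) * nu, size=int(sel.sum()))
    cell_types = panel.names
    infil = np.clip(
        base[None, :] + rng.normal(0.0, 0.05, size=(len(cell_types), n)), 0.0, 1.0
    )
    protumor = np.array([ct in PROTUMOR_ROLES for ct in cell_types])
    antitumor = np.array([ct in ANTITUMOR_ROLES for ct in cell_types])
    boost = protumor[:, None] & (labels == "C3")[None, :]
    infil = np.clip(infil + _PROTUMOR_C3_BOOST * boost, 0.0, 1.0)
    boost1 = antitumor[:, None] & (labels == "C1")[None, :]
    infil = np.clip(infil + _ANTITUMOR_C1_BOOST * boost1, 0.0, 1.0)

    for c, ct in enumerate(cell_types):
        idx = [gene_pos[g] for g in panel[ct] if g in gene_pos]
        log2x[idx, :] += config.infiltration_effect * infil[c][None, :]

    for name in pathways.names:
        scheme = "calcium" if name == "calcium_signaling" else "C3_up"
        act = np.array([_PATHWAY_ACTIVITY[scheme][lb] for lb in labels])
        act = act + rng.normal(0.0, 0.1, size=n)
        idx = [gene_pos[g] for g in pathways[name] if g in gene_pos]
        log2x[idx, :] += config.pathway_effect * act[None, :]

    fpkm = np.clip(2.0**log2x - 1.0, 0.0, None)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    expr = pd.DataFrame(fpkm, index=genes, columns=sample_ids)
    infiltration = pd.DataFrame(infil, index=cell_types, columns=sample_ids)
    return expr, infiltration


def _smooth_noise(
    rng: np.random.Generator, shape: tuple[int, ...], sigma: float
) -> np.ndarray:
    """Gaussian-filtered white noise rescaled to unit variance."""
    raw = rng.normal(size=shape)
    smooth = ndimage.gaussian_filter(raw, sigma)
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _perturb_mask(
    mask: np.ndarray, radius: int, rng: np.random.Generator
) -> np.ndarray:
    """Rater-style perturbation: dilate/erode by <= radius + boundary flips."""
    if radius == 0:
        return mask.copy()
    r = int(rng.integers(0, radius + 1))
    mode = rng.choice(["dilate", "erode", "none"])
    out = mask.copy()
    if r > 0 and mode == "dilate":
        out = ndimage.binary_dilation(out, iterations=r)
    elif r > 0 and mode == "erode":
        eroded = ndimage.binary_erosion(out, iterations=r)
        if eroded.any():
            out = eroded
    boundary = out ^ ndimage.binary_erosion(out)
    b_idx = np.argwhere(boundary)
    n_flip = int(0.05 * len(b_idx))
    if n_flip > 0:
        flip = b_idx[rng.choice(len(b_idx), size=n_flip, replace=False)]
        out[tuple(flip.T)] = ~out[tuple(flip.T)]
    if not out.any():
        return mask.copy()
    return out


def simulate_images(
    labels: np.ndarray | pd.Series,
    batch: np.ndarray | pd.Series,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> tuple[
    dict[str, dict[str, np.ndarray]],
    dict[str, np.ndarray],
    dict[str, np.ndarray],
    dict[str, np.ndarray],
]:
    """Four-channel tumor volumes plus true / second-rater / repeat masks.

    The tumor is an ellipsoid whose intensity mean, rim contrast, internal
    texture correlation length and eccentricity depend on subtype; scanner
    batches apply a channel-wise multiplicative gain and additive offset.
    """
    labels = np.asarray(labels)
    batch = np.asarray(batch)
    shape = tuple(int(s) for s in config.image_shape)
    if min(shape) < 32:
        raise ValueError("image_shape must be at least 32 voxels per axis")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    batches = sorted(set(batch))
    gain = {
        (b, ch): 1.0 + rng.normal(0.0, config.batch_gain_sd)
        for b in batches
        for ch in _CHANNEL_BACKGROUND
    }
    offset = {
        (b, ch): rng.normal(0.0, config.batch_offset_sd)
        for b in batches
        for ch in _CHANNEL_BACKGROUND
    }

    grid = np.stack(
        np.meshgrid(*(np.arange(s, dtype=np.float64) for s in shape), indexing="ij")
    )
    volumes: dict[str, dict[str, np.ndarray]] = {}
    masks: dict[str, np.ndarray] = {}
    masks_r2: dict[str, np.ndarray] = {}
    masks_i2: dict[str, np.ndarray] = {}

    for i, (lb, bt) in enumerate(zip(labels, batch)):
        sid = f"S{i + 1:04d}"
        base_r = rng.uniform(5.0, 8.0) * min(shape) / 32.0
        lo, hi = _ECCENTRICITY[lb]
        radii = base_r * np.array([1.0, rng.uniform(lo, hi), rng.uniform(lo, hi)])
        center = np.array(shape) / 2.0 + rng.uniform(-2.0, 2.0, size=3)
        if np.any(center - radii < 1) or np.any(center + radii > np.array(shape) - 1):
            raise ValueError("tumor does not fit inside the volume")
        dist = (
            ((grid[0] - center[0]) / radii[0]) ** 2
            + ((grid[1] - center[1]) / radii[1]) ** 2
            + ((grid[2] - center[2]) / radii[2]) ** 2
        )
        mask = dist <= 1.0
        rim = mask & ~ndimage.binary_erosion(mask, iterations=2)
        texture = _smooth_noise(rng, shape, _TEXTURE_SIGMA[lb])

        chans: dict[str, np.ndarray] = {}
        for ch, bg in _CHANNEL_BACKGROUND.items():
            scale = _CHANNEL_CONTRAST_SCALE[ch]
            vol = np.full(shape, bg, dtype=np.float64)
            vol[mask] += scale * _TUMOR_CONTRAST[lb]
            vol[rim] += scale * _RIM_CONTRAST[lb]
            vol[mask] += _TEXTURE_AMPLITUDE * texture[mask]
            vol += rng.normal(0.0, _NOISE_SD, size=shape)
            vol = vol * gain[(bt, ch)] + offset[(bt, ch)]
            chans[ch] = vol
        volumes[sid] = chans
        masks[sid] = mask
        masks_r2[sid] = _perturb_mask(mask, config.rater_perturb_radius, rng)
        masks_i2[sid] = _perturb_mask(mask, config.rater_perturb_radius, rng)
    return volumes, masks, masks_r2, masks_i2


def simulate_survival(
    labels: np.ndarray | pd.Series,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Exponential survival with subtype hazards and uniform censoring."""
    labels = np.asarray(labels)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    hazards = dict(zip(SUBTYPES, config.hazard_per_subtype))
    n = len(labels)
    rate = np.array([hazards[lb] for lb in labels])
    event_time = rng.exponential(1.0 / rate)
    censored = rng.uniform(size=n) < config.censor_rate
    observed = np.where(censored, rng.uniform(0.0, 1.0, size=n) * event_time, event_time)
    observed = np.maximum(observed, 1e-3)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    return pd.DataFrame(
        {
            "os_months": observed,
            "os_event": (~censored).astype(int),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )


_GRADE_PROBS = {"C1": (0.2, 0.1, 0.7), "C2": (0.5, 0.2, 0.3), "C3": (0.1, 0.05, 0.85)}


def make_cohort(config: CohortConfig, out_dir: str | Path | None = None) -> SyntheticCohort:
    """Generate a fully aligned cohort; optionally persist it to ``out_dir``."""
    ss = np.random.SeedSequence(config.seed)
    rng_labels, rng_expr, rng_img, rng_surv, rng_misc = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    labels = _draw_labels(config, rng_labels)
    if config.label_noise > 0:
        flip = rng_labels.uniform(size=len(labels)) < config.label_noise
        labels = labels.copy()
        labels[flip] = rng_labels.choice(SUBTYPES, size=int(flip.sum()))

    panel, universe = make_panel(config)
    pathways = make_pathways(config)
    expr, infiltration = simulate_expression(
        panel, pathways, labels, config, rng_expr, universe
    )
    sample_ids = list(expr.columns)
    batch = pd.Series(
        [f"B{rng_misc.integers(1, config.n_batches + 1)}" for _ in sample_ids],
        index=sample_ids,
        name="batch",
    )
    survival = simulate_survival(labels, config, rng_surv)
    grade = [
        int(rng_misc.choice([2, 3, 4], p=_GRADE_PROBS[lb])) for lb in labels
    ]

    volumes: dict[str, dict[str, np.ndarray]] = {}
    masks: dict[str, np.ndarray] = {}
    masks_r2: dict[str, np.ndarray] = {}
    masks_i2: dict[str, np.ndarray] = {}
    if config.with_images:
        volumes, masks, masks_r2, masks_i2 = simulate_images(
            labels, batch.to_numpy(), config, rng_img
        )

    clinical = pd.DataFrame(
        {
            "subtype": labels,
            "os_months": survival["os_months"].to_numpy(),
            "os_event": survival["os_event"].to_numpy(),
            "batch": batch.to_numpy(),
            "grade": grade,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    cohort = SyntheticCohort(
        config=config,
        sample_ids=sample_ids,
        expression=expr,
        panel=panel,
        pathways=pathways,
        role_map=dict(panel.roles),
        true_subtype=pd.Series(labels, index=sample_ids, name="subtype"),
        infiltration=infiltration,
        batch=batch,
        clinical=clinical,
        volumes=volumes,
        masks=masks,
        masks_rater2=masks_r2,
        masks_intra2=masks_i2,
    )
    if out_dir is not None:
        save_cohort(cohort, out_dir)
    return cohort


def save_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Persist a cohort in the standard plain formats (TSV/GMT/CSV/NIfTI)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(cohort.expression, out / "expression.tsv")
    write_gmt(cohort.panel, out / "panel.gmt")
    write_gmt(cohort.pathways, out / "pathways.gmt")
    write_clinical(cohort.clinical, out / "clinical.csv")
    cohort.infiltration.to_csv(out / "true_infiltration.tsv", sep="\t")
    spacing = cohort.config.voxel_spacing
    if cohort.volumes:
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        for sid, chans in cohort.volumes.items():
            for ch, vol in chans.items():
                write_volume(vol, spacing, img_dir / f"{sid}_{ch}.nii.gz")
            write_volume(
                cohort.masks[sid].astype(np.uint8), spacing, img_dir / f"{sid}_mask.nii.gz"
            )
            write_volume(
                cohort.masks_rater2[sid].astype(np.uint8),
                spacing,
                img_dir / f"{sid}_mask_rater2.nii.gz",
            )
            write_volume(
                cohort.masks_intra2[sid].astype(np.uint8),
                spacing,
                img_dir / f"{sid}_mask_intra2.nii.gz",
            )


def load_cohort(directory: str | Path, config: CohortConfig | None = None) -> SyntheticCohort:
    """Read back a cohort written by :func:`save_cohort`."""
    d = Path(directory)
    expr = read_expression(d / "expression.tsv")
    panel = read_gmt(d / "panel.gmt")
    pathways = read_gmt(d / "pathways.gmt")
    clinical = read_clinical(d / "clinical.csv")
    sample_ids = list(clinical.index)
    infiltration = pd.read_csv(d / "true_infiltration.tsv", sep="\t", index_col=0)
    # role tags equal the canonical cell-type names for the nine scored roles
    roles = {
        name: name if name in (*PROTUMOR_ROLES, *ANTITUMOR_ROLES) else "other"
        for name in panel.names
    }
    panel.roles = roles
    volumes: dict[str, dict[str, np.ndarray]] = {}
    masks: dict[str, np.ndarray] = {}
    masks_r2: dict[str, np.ndarray] = {}
    masks_i2: dict[str, np.ndarray] = {}
    img_dir = d / "images"
    if img_dir.exists():
        for sid in sample_ids:
            chans = {}
            for ch in _CHANNEL_BACKGROUND:
                vol, mask, _ = read_volume_mask(
                    img_dir / f"{sid}_{ch}.nii.gz", img_dir / f"{sid}_mask.nii.gz"
                )
                chans[ch] = vol
                masks[sid] = mask
            volumes[sid] = chans
            _, masks_r2[sid], _ = read_volume_mask(
                img_dir / f"{sid}_T1.nii.gz", img_dir / f"{sid}_mask_rater2.nii.gz"
            )
            _, masks_i2[sid], _ = read_volume_mask(
                img_dir / f"{sid}_T1.nii.gz", img_dir / f"{sid}_mask_intra2.nii.gz"
            )
    if config is None:
        config = CohortConfig(n_samples=len(sample_ids))
    return SyntheticCohort(
        config=config,
        sample_ids=sample_ids,
        expression=expr,
        panel=panel,
        pathways=pathways,
        role_map=roles,
        true_subtype=clinical["subtype"],
        infiltration=infiltration,
        batch=clinical["batch"],
        clinical=clinical,
        volumes=volumes,
        masks=masks,
        masks_rater2=masks_r2,
        masks_intra2=masks_i2,
    )
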