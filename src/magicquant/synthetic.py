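"""Ground-truthed synthetic data for every stage of the pipeline.

Four generators emulate the data regimes the analysis assumes, each a pure
function of its parameters (including the seed):

* ``generate_scene`` — two-channel confocal z-stacks of yeast-sized cells
  with tubular mitochondrial mCherry and condition-dependent matrix spGFP;
* ``generate_screen_plate`` — per-cell flow/imaging draws for a knockout
  plate with planted Class 1 / Class 2 / null strains;
* ``generate_event_table`` — single-cell flow intensities as a two-component
  log-normal spGFP mixture with a membrane-potential (TMRM) channel;
* ``generate_nucleocyto_image`` — a nuclear-marker + reporter image pair
  with a known nuclear:cytoplasmic reporter ratio.

Every generator returns the ground truth (masks, labels, planted classes,
true fractions) alongside the data, so downstream estimates can be checked
against what was actually simulated.  No photophysics is modelled: there is
no PSF, bleaching, or mitochondrial motion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .image_quant import ZStack

CONDITION_30C = "PERMISSIVE_30C"
CONDITION_HS = "HEAT_SHOCK_42C"

CLASS1 = "CLASS1"
CLASS2 = "CLASS2"
NULL = "NULL"
EXCLUDED = "EXCLUDED"

_MAX_PLACEMENT_ATTEMPTS = 1000


@dataclass(frozen=True)
class ImagingParams:
    """Stated world of the confocal generator.

    Defaults emulate spinning-disc yeast stacks: 12 z-planes (0.5 um step
    over 6 um), ~8 px cell radius at 256x256, mitochondria covering ~30% of
    the projected cell area, spGFP well above the cytosolic floor, and mild
    additive camera noise.  Intensities are arbitrary units stored as
    unsigned 16-bit.  The default 50 cells give the ~15% field coverage of
    a crowded mid-log imaging field; the percentile-seeded background
    segmentation assumes cells cover more than ~10% of the field.
    """

    image_shape: tuple[int, int, int] = (12, 256, 256)
    cell_count: int = 50
    cell_radius_px: tuple[float, float] = (8.0, 1.0)  # (mean, sd)
    mito_fraction: float = 0.3
    gfp_mito_mean: float = 40.0
    gfp_cyto_mean: float = 8.0
    mcherry_mito_mean: float = 120.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.image_shape) != 3 or any(d < 1 for d in self.image_shape):
            raise ValueError("image_shape must be three dims, each >= 1")
        if self.cell_count < 0:
            raise ValueError("cell_count must be >= 0")
        if not 0.0 < self.mito_fraction < 1.0:
            raise ValueError("mito_fraction must be in (0, 1)")
        for name in ("gfp_mito_mean", "gfp_cyto_mean", "mcherry_mito_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticScene:
    zstack: ZStack
    cell_truth: np.ndarray  # 2-D labels, 0 = background
    mito_truth: np.ndarray  # 2-D bool, subset of cell_truth support
    per_cell_true_spgfp: dict[int, float]
    params: ImagingParams


@dataclass(frozen=True)
class ScreenEffectSizes:
    """Planted effects, as multipliers on the wild-type baseline.

    class1_ratio_shift scales the 30 C spGFP mean of Class 1 strains (their
    baseline spGFP/mCherry ratio is elevated vs WT); hs_fold is the normal
    heat-shock spGFP increase shown by WT and null strains (Class 2 strains
    lack it: their heat-shock mean equals baseline, fold change 1.0).
    """

    class1_ratio_shift: float = 2.0
    hs_fold: float = 1.5

    def __post_init__(self) -> None:
        if self.class1_ratio_shift <= 0 or self.hs_fold <= 0:
            raise ValueError("effect sizes must be > 0")


@dataclass(frozen=True)
class ScreenPlateTruth:
    strain_id: str
    true_class: str
    baseline_mean: float
    hs_mean: float
    per_cell_params: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class FlowSimParams:
    """Log-normal spGFP mixture with a TMRM channel.

    The negative (autofluorescence) and positive components are ~20-fold
    apart on the intensity scale — the kind of separation a matrix-
    reconstituted spGFP reporter shows on a flow cytometer.  ``tmrm_shift``
    is added to the TMRM intensity of positive events (negative values model
    depolarization of the importing subpopulation).
    """

    n_events: int = 25_000
    positive_fraction: float = 0.0
    neg_log_mean: float = 4.0
    neg_log_sd: float = 0.5
    pos_log_mean: float = 7.0
    pos_log_sd: float = 0.5
    tmrm_log_mean: float = 5.0
    tmrm_log_sd: float = 0.4
    tmrm_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in [0, 1]")
        for name in ("neg_log_sd", "pos_log_sd", "tmrm_log_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class NucCytoScene:
    reporter: np.ndarray
    nuclear_marker: np.ndarray
    nuclear_truth: np.ndarray  # labels, one nucleus per cell
    cell_truth: np.ndarray  # labels
    nc_ratio_true: float


# ---------------------------------------------------------------------------
# cell placement helpers


def _ellipse_mask(shape, center, radii, theta) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    y = yy - center[0]
    x = xx - center[1]
    c, s = np.cos(theta), np.sin(theta)
    u = c * x + s * y
    v = -s * x + c * y
    return (u / radii[1]) ** 2 + (v / radii[0]) ** 2 <= 1.0


def _place_cells(
    rng: np.random.Generator,
    shape: tuple[int, int],
    count: int,
    radius_mean: float,
    radius_sd: float,
    eccentric: bool = True,
) -> np.ndarray:
    """Non-overlapping ellipses by rejection sampling (1-px gap enforced)."""
    labels = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)
    margin = int(np.ceil(radius_mean + 3 * radius_sd)) + 1
    for k in range(1, count + 1):
        for attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            cy = rng.uniform(margin, shape[0] - margin)
            cx = rng.uniform(margin, shape[1] - margin)
            a = max(3.0, rng.normal(radius_mean, radius_sd))
            b = max(3.0, rng.normal(radius_mean, radius_sd)) if eccentric else a
            theta = rng.uniform(0, np.pi) if eccentric else 0.0
            mask = _ellipse_mask(shape, (cy, cx), (a, b), theta)
            if not mask.any():
                continue
            # dilated overlap check keeps a >=1 px background gap
            if (ndi.binary_dilation(mask) & occupied).any():
                continue
            labels[mask] = k
            occupied |= mask
            break
        else:
            raise RuntimeError(
                f"could not place cell {k} of {count} after "
                f"{_MAX_PLACEMENT_ATTEMPTS} attempts; reduce cell_count or "
                "enlarge the image"
            )
    return labels


def _tubular_mito(
    rng: np.random.Generator, cell_mask: np.ndarray, fraction: float
) -> np.ndarray:
    """Tubular mitochondrial network: dilated random walks inside the cell."""
    target = max(1, int(round(fraction * cell_mask.sum())))
    coords = np.argwhere(cell_mask)
    mito = np.zeros_like(cell_mask)
    n_segments = int(rng.integers(2, 6))
    steps = np.array([[dy, dx] for dy in (-1, 0, 1) for dx in (-1, 0, 1) if dy or dx])
    for _ in range(200):  # cap: keep generation bounded
        for _ in range(n_segments):
            pos = coords[rng.integers(len(coords))]
            length = int(rng.integers(5, 20))
            for _ in range(length):
                mito[pos[0], pos[1]] = True
                step = steps[rng.integers(len(steps))]
                nxt = pos + step
                if cell_mask[nxt[0], nxt[1]]:
                    pos = nxt
            if mito.sum() >= target:
                break
        mito = ndi.binary_dilation(mito) & cell_mask
        if mito.sum() >= target:
            break
    return mito


def generate_scene(params: ImagingParams) -> SyntheticScene:
    """Render a two-channel z-stack with per-cell ground truth.

    mCherry is bright only on the mitochondrial truth mask; GFP mixes a
    cytosolic floor with a per-cell mitochondrial spGFP level (the stored
    truth, an integer so zero-noise stacks recover it exactly after the
    uint16 round-trip).  Per-plane values are constant, so the z-sum of a
    mitochondrial pixel is ``true_spgfp * n_planes``.  Gaussian noise is
    added per voxel, clipped at zero, and stored as uint16.
    """
    nz, ny, nx = params.image_shape
    radius_mean, radius_sd = params.cell_radius_px
    diameter = int(np.ceil(2 * (radius_mean + 3 * radius_sd)))
    if params.cell_count > 0:
        for name, dim in (("y", ny), ("x", nx)):
            if dim < diameter + 2:
                raise ValueError(
                    f"image {name} dimension ({dim}) smaller than cell "
                    f"diameter ({diameter})"
                )

    rng = np.random.default_rng(params.seed)
    cell_truth = _place_cells(rng, (ny, nx), params.cell_count, radius_mean, radius_sd)
    mito_truth = np.zeros((ny, nx), dtype=bool)
    per_cell_true: dict[int, float] = {}

    gfp_plane = np.zeros((ny, nx), dtype=np.float64)
    mch_plane = np.zeros((ny, nx), dtype=np.float64)
    for k in range(1, params.cell_count + 1):
        cell = cell_truth == k
        mito = _tubular_mito(rng, cell, params.mito_fraction)
        mito_truth |= mito
        true_spgfp = float(
            max(1.0, round(rng.normal(params.gfp_mito_mean, 0.2 * params.gfp_mito_mean)))
        )
        per_cell_true[k] = true_spgfp
        gfp_plane[cell] = params.gfp_cyto_mean
        gfp_plane[mito] = true_spgfp
        mch_plane[mito] = params.mcherry_mito_mean

    gfp = np.broadcast_to(gfp_plane, (nz, ny, nx)).copy()
    mch = np.broadcast_to(mch_plane, (nz, ny, nx)).copy()
    if params.noise_sd > 0:
        gfp += rng.normal(0.0, params.noise_sd, size=gfp.shape)
        mch += rng.normal(0.0, params.noise_sd, size=mch.shape)
    gfp = np.clip(np.round(gfp), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    mch = np.clip(np.round(mch), 0, np.iinfo(np.uint16).max).astype(np.uint16)

    return SyntheticScene(
        zstack=ZStack(gfp=gfp, mcherry=mch),
        cell_truth=cell_truth,
        mito_truth=mito_truth,
        per_cell_true_spgfp=per_cell_true,
        params=params,
    )


def write_scene(scene: SyntheticScene, out_dir) -> dict[str, str]:
    """Write the scene as two multi-page TIFFs plus truth TIFFs and a JSON sidecar."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gfp": str(out / "gfp.tif"),
        "mcherry": str(out / "mcherry.tif"),
        "cell_truth": str(out / "cell_truth.tif"),
        "mito_truth": str(out / "mito_truth.tif"),
        "truth_json": str(out / "truth.json"),
    }
    tifffile.imwrite(paths["gfp"], scene.zstack.gfp)
    tifffile.imwrite(paths["mcherry"], scene.zstack.mcherry)
    tifffile.imwrite(paths["cell_truth"], scene.cell_truth.astype(np.uint16))
    tifffile.imwrite(paths["mito_truth"], scene.mito_truth.astype(np.uint8))
    sidecar = {
        "params": asdict(scene.params),
        "per_cell_true_spgfp": {str(k): v for k, v in scene.per_cell_true_spgfp.items()},
    }
    Path(paths["truth_json"]).write_text(json.dumps(sidecar, indent=2))
    return paths


# ---------------------------------------------------------------------------
# knockout screen plate


def generate_screen_plate(
    n_strains: int,
    n_class1: int,
    n_class2: int,
    cells_per_strain: int = 200,
    effect_sizes: ScreenEffectSizes = ScreenEffectSizes(),
    seed: int = 0,
    wt_strain_id: str = "WT",
    spgfp_mean: float = 50.0,
    spgfp_sd: float = 15.0,
    mcherry_mean: float = 100.0,
    mcherry_sd: float = 10.0,
) -> tuple[pd.DataFrame, list[ScreenPlateTruth]]:
    """Per-cell spGFP/mCherry draws for a planted knockout plate.

    Returns a tidy table (strain_id, condition, spgfp, mcherry) covering the
    designated wild-type strain plus ``n_strains`` knockouts, and the truth
    list.  Class assignment: the first ``n_class1`` knockouts carry the
    elevated-baseline effect, the next ``n_class2`` lack the heat-shock
    increase, the rest behave like wild type.  Draws are normal, clipped at
    zero (intensities cannot be negative).
    """
    if n_class1 + n_class2 > n_strains:
        raise ValueError("n_class1 + n_class2 must be <= n_strains")
    if cells_per_strain < 1:
        raise ValueError("cells_per_strain must be >= 1")
    rng = np.random.default_rng(seed)

    strains = [wt_strain_id] + [f"YKO{i:05d}" for i in range(1, n_strains + 1)]
    classes = [NULL]  # wild type behaves as a null strain
    classes += [CLASS1] * n_class1 + [CLASS2] * n_class2
    classes += [NULL] * (n_strains - n_class1 - n_class2)

    frames = []
    truth: list[ScreenPlateTruth] = []
    n = cells_per_strain
    for sid, cls in zip(strains, classes):
        base_mu = spgfp_mean * (
            effect_sizes.class1_ratio_shift if cls == CLASS1 else 1.0
        )
        hs_mu = base_mu * (1.0 if cls == CLASS2 else effect_sizes.hs_fold)
        spgfp_30 = np.clip(rng.normal(base_mu, spgfp_sd, n), 0, None)
        spgfp_hs = np.clip(rng.normal(hs_mu, spgfp_sd, n), 0, None)
        mch_30 = np.clip(rng.normal(mcherry_mean, mcherry_sd, n), 1e-6, None)
        mch_hs = np.clip(rng.normal(mcherry_mean, mcherry_sd, n), 1e-6, None)
        frames.append(
            pd.DataFrame(
                {
                    "strain_id": sid,
                    "condition": [CONDITION_30C] * n + [CONDITION_HS] * n,
                    "spgfp": np.concatenate([spgfp_30, spgfp_hs]),
                    "mcherry": np.concatenate([mch_30, mch_hs]),
                }
            )
        )
        truth.append(
            ScreenPlateTruth(
                strain_id=sid,
                true_class=NULL if sid == wt_strain_id else cls,
                baseline_mean=base_mu,
                hs_mean=hs_mu,
                per_cell_params={
                    "spgfp_sd": spgfp_sd,
                    "mcherry_mean": mcherry_mean,
                    "mcherry_sd": mcherry_sd,
                },
            )
        )
    cells = pd.concat(frames, ignore_index=True)
    return cells, truth


def plate_flow_summaries(
    cells: pd.DataFrame, background: float = 0.0
) -> pd.DataFrame:
    """Population-mean flow summaries per strain (raw means include background).

    Emulates the primary flow readout of a screen plate: the mean spGFP of
    all cells of a strain before and after heat shock, on an instrument
    scale offset by a constant background.
    """
    g = cells.groupby(["strain_id", "condition"])["spgfp"].mean().unstack()
    out = pd.DataFrame(
        {
            "strain_id": g.index,
            "mean_spgfp_30C": g[CONDITION_30C].to_numpy() + background,
            "mean_spgfp_HS": g[CONDITION_HS].to_numpy() + background,
            "background": background,
        }
    ).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# flow-cytometry event tables


def generate_event_table(params: FlowSimParams) -> pd.DataFrame:
    """Single-cell flow events: spGFP mixture, mCherry, TMRM.

    Columns: spgfp, mcherry, tmrm, true_positive (ground-truth component
    label, ignored by the gating stage).  Positive events take the high
    log-normal spGFP component and a TMRM intensity shifted by
    ``tmrm_shift`` (clipped at zero).
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_events
    positive = rng.random(n) < params.positive_fraction
    spgfp = np.where(
        positive,
        rng.lognormal(params.pos_log_mean, params.pos_log_sd, n),
        rng.lognormal(params.neg_log_mean, params.neg_log_sd, n),
    )
    mcherry = rng.lognormal(4.5, 0.3, n)
    tmrm = rng.lognormal(params.tmrm_log_mean, params.tmrm_log_sd, n)
    tmrm = np.clip(tmrm + np.where(positive, params.tmrm_shift, 0.0), 0.0, None)
    return pd.DataFrame(
        {"spgfp": spgfp, "mcherry": mcherry, "tmrm": tmrm, "true_positive": positive}
    )


# ---------------------------------------------------------------------------
# nucleocytoplasmic reporter images


def generate_nucleocyto_image(
    nc_ratio_true: float,
    shape: tuple[int, int] = (256, 256),
    seed: int = 0,
    n_cells: int = 12,
    cell_radius_px: float = 14.0,
    nucleus_radius_px: float = 4.0,
    cyto_intensity: float = 100.0,
    marker_intensity: float = 200.0,
    noise_sd: float = 0.0,
) -> NucCytoScene:
    """Reporter + nuclear-marker image pair with known N/C ratio.

    Cells are discs with a concentric nuclear disc.  Before noise, the
    reporter is ``cyto_intensity`` in the cytoplasm and
    ``cyto_intensity * nc_ratio_true`` in the nucleus; the marker channel is
    bright only on nuclei.  Arrays are float64 so the noise-free ratio is
    exact.
    """
    if nc_ratio_true <= 0:
        raise ValueError("nc_ratio_true must be > 0")
    if nucleus_radius_px >= cell_radius_px:
        raise ValueError(
            f"nucleus radius ({nucleus_radius_px}) must be smaller than the "
            f"cell radius ({cell_radius_px})"
        )
    rng = np.random.default_rng(seed)
    cell_truth = _place_cells(
        rng, shape, n_cells, cell_radius_px, 0.05 * cell_radius_px, eccentric=False
    )
    nuclear_truth = np.zeros(shape, dtype=np.int32)
    reporter = np.zeros(shape, dtype=np.float64)
    marker = np.zeros(shape, dtype=np.float64)
    for k in range(1, n_cells + 1):
        cell = cell_truth == k
        cy, cx = ndi.center_of_mass(cell)
        nucleus = _ellipse_mask(
            shape, (cy, cx), (nucleus_radius_px, nucleus_radius_px), 0.0
        ) & cell
        nuclear_truth[nucleus] = k
        reporter[cell] = cyto_intensity
        reporter[nucleus] = cyto_intensity * nc_ratio_true
        marker[nucleus] = marker_intensity
    if noise_sd > 0:
        reporter = np.clip(reporter + rng.normal(0, noise_sd, shape), 0, None)
        marker = np.clip(marker + rng.normal(0, noise_sd, shape), 0, None)
    return NucCytoScene(
        reporter=reporter,
        nuclear_marker=marker,
        nuclear_truth=nuclear_truth,
        cell_truth=cell_truth,
        nc_ratio_true=float(nc_ratio_true),
    )
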