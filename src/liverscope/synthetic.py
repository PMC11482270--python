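"""Seeded synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analyses assume —
a multi-type single-cell reference with planted per-type markers, bulk
libraries that are mixtures of the reference mean profiles with known
proportions, differential-expression tables with planted up/down genes,
and section-like images with bright elliptical droplets of known area on a
stained background.  All generators are pure functions of their parameters
and seed; the returned truth objects are sufficient to score recovery
without re-simulation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, PlacementError
from .histomorphometry import CalibratedImage, DEFAULT_PIXEL_AREA_UM2
from .reference_prep import ReferenceCellAtlas


@dataclass
class SimulationTruth:
    """Ground truth planted by a generator."""

    seed: int
    planted_markers: dict[str, list[str]] = field(default_factory=dict)
    marker_effect_fold: float | None = None
    true_fractions: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_up: list[str] = field(default_factory=list)
    planted_down: list[str] = field(default_factory=list)
    planted_disks: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts via the gamma-Poisson mixture.

    ``dispersion`` is the NB overdispersion alpha: variance = mu + alpha mu².
    alpha = 0 degenerates to Poisson.
    """
    if dispersion < 0:
        raise ConfigurationError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_reference(
    n_types: int = 5,
    n_genes: int = 500,
    markers_per_type: int = 20,
    cells_per_type: int = 100,
    n_samples: int = 3,
    effect_fold: float = 10.0,
    dispersion: float = 0.3,
    seed: int = 0,
    count_model: str = "nb",
) -> tuple[ReferenceCellAtlas, SimulationTruth]:
    """Single-cell reference with planted per-type marker genes.

    Baseline gene means are lognormal; the ``markers_per_type`` genes
    assigned to each type have their mean multiplied by ``effect_fold`` in
    cells of that type only.  Counts are negative-binomial (``count_model
    = 'poisson'`` for Poisson) and cells are assigned uniformly at random
    to ``n_samples`` donors.
    """
    if markers_per_type * n_types > n_genes:
        raise ConfigurationError("markers_per_type * n_types exceeds n_genes")
    if min(n_types, n_genes, cells_per_type, n_samples) < 1:
        raise ConfigurationError("all dimensions must be >= 1")
    if count_model not in ("nb", "poisson"):
        raise ConfigurationError(f"unknown count model {count_model!r}")
    rng = np.random.default_rng(seed)

    genes = [f"g{i:04d}" for i in range(n_genes)]
    types = [f"type{t}" for t in range(n_types)]
    samples = [f"donor{s}" for s in range(n_samples)]

    base_mean = rng.lognormal(mean=0.7, sigma=0.6, size=n_genes)
    planted: dict[str, list[str]] = {}
    type_means = np.tile(base_mean[:, None], (1, n_types))
    for t in range(n_types):
        lo, hi = t * markers_per_type, (t + 1) * markers_per_type
        type_means[lo:hi, t] *= effect_fold
        planted[types[t]] = genes[lo:hi]

    disp = 0.0 if count_model == "poisson" else dispersion
    blocks, cell_ids, cell_types, sample_ids = [], [], [], []
    for t in range(n_types):
        mu = np.tile(type_means[:, t][:, None], (1, cells_per_type))
        blocks.append(_nb_counts(rng, mu, disp))
        for c in range(cells_per_type):
            cell_ids.append(f"c{t}_{c:04d}")
            cell_types.append(types[t])
        sample_ids.extend(rng.choice(samples, size=cells_per_type).tolist())

    counts = pd.DataFrame(
        np.concatenate(blocks, axis=1),
        index=pd.Index(genes, name="gene"),
        columns=cell_ids,
    )
    obs = pd.DataFrame(
        {"cell_type": cell_types, "sample_id": sample_ids},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    truth = SimulationTruth(
        seed=seed, planted_markers=planted, marker_effect_fold=effect_fold
    )
    return ReferenceCellAtlas(counts=counts, obs=obs), truth


def mean_profiles(atlas: ReferenceCellAtlas) -> pd.DataFrame:
    """Per-type mean raw count profiles (genes x cell types)."""
    return atlas.counts.T.groupby(atlas.obs["cell_type"], observed=True).mean().T


def simulate_bulk(
    reference_profiles: pd.DataFrame,
    fractions: pd.DataFrame,
    depth: int = 1_000_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Bulk counts as multinomial draws from mixtures of type profiles.

    ``fractions`` is samples x cell types (rows on the simplex); the
    expected expression of a sample is the fraction-weighted sum of the
    reference mean profiles, sampled at the given sequencing ``depth``.
    """
    if depth <= 0:
        raise ConfigurationError("depth must be positive")
    fr = fractions.to_numpy(dtype=float)
    if (fr < 0).any() or not np.allclose(fr.sum(axis=1), 1.0, atol=1e-9):
        raise ConfigurationError("fraction rows must be nonnegative and sum to 1")
    missing = fractions.columns.difference(reference_profiles.columns)
    if len(missing):
        raise ConfigurationError(f"profiles lack cell types {list(missing)}")
    rng = np.random.default_rng(seed)

    profiles = reference_profiles[fractions.columns].to_numpy(dtype=float)
    expected = profiles @ fr.T  # genes x samples
    cols = {}
    for j, sample in enumerate(fractions.index):
        p = expected[:, j] / expected[:, j].sum()
        cols[sample] = rng.multinomial(int(depth), p)
    counts = pd.DataFrame(cols, index=reference_profiles.index)
    truth = SimulationTruth(
        seed=seed,
        true_fractions={
            str(s): {str(t): float(v) for t, v in row.items()}
            for s, row in fractions.iterrows()
        },
    )
    return counts, truth


def simulate_de_table(
    n_genes: int = 2000,
    n_up: int = 150,
    n_down: int = 150,
    fc_range: tuple[float, float] = (1.5, 8.0),
    seed: int = 0,
    gene_symbols: list[str] | None = None,
    up_genes: list[str] | None = None,
    down_genes: list[str] | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """DE table with planted significant up/down genes.

    Fold changes are signed linear (|FC| >= 1; -2 means halved).  Planted
    genes get |FC| in ``fc_range`` and adjusted p < 0.05; null genes fail
    at least one criterion (half are non-significant, half have
    |FC| < 1.5).  Explicit ``up_genes`` / ``down_genes`` override the
    random choice of planted symbols.
    """
    if gene_symbols is None:
        gene_symbols = [f"g{i:04d}" for i in range(n_genes)]
    n_genes = len(gene_symbols)
    rng = np.random.default_rng(seed)

    if up_genes is None or down_genes is None:
        if n_up + n_down > n_genes:
            raise ConfigurationError("n_up + n_down exceeds n_genes")
        order = rng.permutation(n_genes)
        up_genes = [gene_symbols[i] for i in order[:n_up]]
        down_genes = [gene_symbols[i] for i in order[n_up : n_up + n_down]]
    up_set, down_set = set(up_genes), set(down_genes)
    if up_set & down_set:
        raise ConfigurationError("up and down gene lists overlap")

    lo, hi = fc_range
    if lo < 1.5:
        raise ConfigurationError("fc_range must start at >= 1.5 for planted genes")
    fcs, ps = [], []
    for g in gene_symbols:
        if g in up_set:
            fcs.append(rng.uniform(lo, hi))
            ps.append(rng.uniform(1e-8, 0.0499))
        elif g in down_set:
            fcs.append(-rng.uniform(lo, hi))
            ps.append(rng.uniform(1e-8, 0.0499))
        elif rng.random() < 0.5:  # null: not significant
            fcs.append(rng.uniform(1.0, hi) * rng.choice([-1.0, 1.0]))
            ps.append(rng.uniform(0.05, 1.0))
        else:  # null: too small a fold change
            fcs.append(rng.uniform(1.0, 1.49) * rng.choice([-1.0, 1.0]))
            ps.append(rng.uniform(0.0, 1.0))
    table = pd.DataFrame({"gene": gene_symbols, "fold_change": fcs, "adjusted_p": ps})
    truth = SimulationTruth(
        seed=seed, planted_up=sorted(up_set), planted_down=sorted(down_set)
    )
    return table, truth


def simulate_section_image(
    width: int = 256,
    height: int = 256,
    radii: tuple[float, ...] = (6, 8, 10, 12, 15),
    background_level: int = 120,
    foreground_level: int = 240,
    noise_sd: float = 10.0,
    pixel_area: float = DEFAULT_PIXEL_AREA_UM2,
    seed: int = 0,
    margin: int = 3,
    max_tries: int = 2000,
) -> tuple[CalibratedImage, SimulationTruth]:
    """Grayscale section-like image with non-touching bright disks.

    Disks of the given radii (pixels) are placed by rejection sampling so
    no two touch (center distance > r_i + r_j + ``margin``); the image is
    ``background_level`` with disks at ``foreground_level`` plus Gaussian
    pixel noise, clipped to [0, 255].  The truth records each disk's
    center, radius, rasterized pixel count and physical area.
    """
    if not (0 <= background_level <= 255 and 0 <= foreground_level <= 255):
        raise ConfigurationError("levels must be in [0, 255]")
    rng = np.random.default_rng(seed)
    img = np.full((height, width), float(background_level))
    rr, cc = np.mgrid[0:height, 0:width]

    placed: list[tuple[float, float, float]] = []
    disks = []
    for r in sorted(radii, reverse=True):
        ok = False
        for _ in range(max_tries):
            cy = rng.uniform(r + 1, height - r - 1)
            cx = rng.uniform(r + 1, width - r - 1)
            if all(
                np.hypot(cy - py, cx - px) > r + pr + margin for py, px, pr in placed
            ):
                ok = True
                break
        if not ok:
            raise PlacementError(f"could not place a disk of radius {r}")
        placed.append((cy, cx, r))
        mask = (rr - cy) ** 2 + (cc - cx) ** 2 <= r**2
        img[mask] = float(foreground_level)
        disks.append({
            "center_row": float(cy),
            "center_col": float(cx),
            "radius_px": float(r),
            "area_px": int(mask.sum()),
            "area_um2": float(mask.sum() * pixel_area),
        })

    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = SimulationTruth(seed=seed, planted_disks=disks)
    return CalibratedImage(pixels=img, pixel_area=pixel_area), truth
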