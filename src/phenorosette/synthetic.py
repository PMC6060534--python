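"""Synthetic images and tables with known ground truth.

Every generator is deterministic given its seed and returns, next to the
artifact, a ``truth`` dict holding the quantities a test can check against
(pixel areas counted on the rendered mask, fruit counts, logistic
parameters, variance components, the generating coefficients) plus the
seed and parameters that produced it.

The image generators emulate the two kinds of photographs the pipeline
consumes: green rosettes (radial elliptical leaves) on a dark background,
optionally arranged on a pot grid, and thin branching inflorescences in
which every fruit (silique) is rendered as a short lateral segment off a
stem or side branch.  Fruit attachment points are kept at least 7 px apart
so that, after thinning, each fruit contributes exactly one triple point —
the geometric assumption that makes fruit number learnable from skeleton
descriptors.  Mass noise is multiplicative (coefficient of variation),
trait-table noise additive Gaussian, matching how biological measurement
error scales.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.draw import ellipse as _draw_ellipse
from skimage.draw import line as _draw_line
from skimage.morphology import dilation, disk

from .growth import MassSeries

__all__ = [
    "gen_rosette_image",
    "gen_tray_image",
    "gen_inflorescence_image",
    "gen_training_table",
    "gen_growth_series",
    "gen_trait_table",
    "PLANT_COLOR",
    "BACKGROUND_COLOR",
]

PLANT_COLOR = (30, 120, 40)  # leaf green
BACKGROUND_COLOR = (25, 22, 18)  # dark soil

_FRUIT_LEN = 9  # px, pedicel + silique rendered as one lateral stub
_FRUIT_SPACING = 7  # px between attachment points (>= 5 avoids merging)
_THICKNESS_RADIUS = 1  # dilation radius -> 3-px-thick organs


def _paint(mask: np.ndarray) -> np.ndarray:
    """Render a boolean mask as an RGB image (plant on dark soil)."""
    img = np.empty(mask.shape + (3,), dtype=np.uint8)
    img[...] = BACKGROUND_COLOR
    img[mask] = PLANT_COLOR
    return img


def _rosette_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    n_leaves: int,
    leaf_len_px: float,
    leaf_width_px: float,
    jitter: float,
    rng: np.random.Generator,
) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    cy, cx = center
    for k in range(n_leaves):
        angle = 2 * np.pi * k / n_leaves
        if jitter > 0:
            angle += rng.normal(0, jitter)
            length = leaf_len_px * (1 + rng.normal(0, jitter))
            width = leaf_width_px * (1 + rng.normal(0, jitter))
        else:
            length, width = leaf_len_px, leaf_width_px
        length = max(length, 2.0)
        width = max(width, 2.0)
        # leaf = ellipse centered halfway along its own axis
        ecy = cy + (length / 2) * np.sin(angle)
        ecx = cx + (length / 2) * np.cos(angle)
        rr, cc = _draw_ellipse(
            ecy,
            ecx,
            length / 2,
            width / 2,
            shape=shape,
            rotation=-(angle - np.pi / 2),
        )
        mask[rr, cc] = True
    return mask


def gen_rosette_image(
    n_leaves: int = 8,
    leaf_len_px: float = 40,
    leaf_width_px: float = 14,
    jitter: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, dict]:
    """One rosette: green elliptical leaves arranged radially.

    Truth records the pixel area counted directly on the rendered mask,
    plus the mask itself, the parameters and the seed.
    """
    if n_leaves < 1:
        raise ValueError("n_leaves must be >= 1")
    rng = np.random.default_rng(seed)
    if shape is None:
        half = int(np.ceil(leaf_len_px * 1.6)) + 6
        shape = (2 * half, 2 * half)
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    mask = _rosette_mask(
        shape, center, n_leaves, leaf_len_px, leaf_width_px, jitter, rng
    )
    truth = {
        "area_px": int(mask.sum()),
        "mask": mask,
        "center": center,
        "n_leaves": n_leaves,
        "leaf_len_px": leaf_len_px,
        "leaf_width_px": leaf_width_px,
        "jitter": jitter,
        "seed": seed,
    }
    return _paint(mask), truth


def gen_tray_image(
    grid_rows: int,
    grid_cols: int,
    plant_params: list[dict | None] | None = None,
    cell_px: int = 120,
    seed: int = 0,
) -> tuple[np.ndarray, list[dict]]:
    """A tray: one rosette per pot-grid cell (None = empty pot).

    ``plant_params`` lists per-cell keyword dicts for the rosette
    generator, row-major; missing entries default to a medium rosette.
    Truth is a list of per-cell dicts with the cell, pixel area and
    parameters (empty cells record area 0).
    """
    rng = np.random.default_rng(seed)
    n_cells = grid_rows * grid_cols
    if plant_params is None:
        plant_params = [{} for _ in range(n_cells)]
    if len(plant_params) != n_cells:
        raise ValueError("plant_params must have grid_rows*grid_cols entries")
    shape = (grid_rows * cell_px, grid_cols * cell_px)
    mask = np.zeros(shape, dtype=bool)
    truths = []
    for idx, params in enumerate(plant_params):
        row, col = divmod(idx, grid_cols)
        entry = {"cell": (row, col), "area_px": 0, "params": params}
        if params is not None:
            p = {
                "n_leaves": 8,
                "leaf_len_px": 0.28 * cell_px,
                "leaf_width_px": 0.1 * cell_px,
                "jitter": 0.0,
            }
            p.update(params)
            center = ((row + 0.5) * cell_px, (col + 0.5) * cell_px)
            leaf = _rosette_mask(
                shape,
                center,
                p["n_leaves"],
                p["leaf_len_px"],
                p["leaf_width_px"],
                p["jitter"],
                rng,
            )
            entry["area_px"] = int(leaf.sum())
            entry["params"] = p
            mask |= leaf
        truths.append(entry)
    return _paint(mask), truths


def _thick_line(
    mask: np.ndarray, p0: tuple[int, int], p1: tuple[int, int]
) -> None:
    rr, cc = _draw_line(p0[0], p0[1], p1[0], p1[1])
    ok = (rr >= 0) & (rr < mask.shape[0]) & (cc >= 0) & (cc < mask.shape[1])
    mask[rr[ok], cc[ok]] = True


def gen_inflorescence_image(
    n_fruits: int,
    n_side_branches: int = 0,
    stem_len_px: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """A flattened inflorescence: 3-px-thick main stem, optional diagonal
    side branches, and one short lateral stub per fruit.

    Attachment points are spaced >= 7 px apart, so after thinning each
    fruit contributes exactly one triple point and each side-branch
    attachment one more; truth records ``n_fruits``, ``n_side_branches``
    and ``expected_triple_points = n_fruits + n_side_branches``.  Raises
    if the requested fruits do not fit on the stem and branches.
    """
    if n_fruits < 0 or n_side_branches < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    if stem_len_px is None:
        # conservative sizing: every fruit and branch gets a stem slot
        stem_len_px = max(
            80, 24 + _FRUIT_SPACING * (n_fruits + 2 * n_side_branches + 2)
        )

    margin = 14
    branch_len = int(min(0.45 * stem_len_px, 90))
    height = stem_len_px + 2 * margin
    width = 2 * (branch_len + _FRUIT_LEN + 2 * margin) + 3
    mask = np.zeros((height, width), dtype=bool)
    x0 = width // 2
    y_bot, y_top = height - margin, height - margin - stem_len_px
    _thick_line(mask, (y_bot, x0), (y_top, x0))

    # attachment slots along the stem, >= spacing apart, away from the ends
    slot_ys = list(
        range(y_top + _FRUIT_SPACING, y_bot - _FRUIT_SPACING, _FRUIT_SPACING)
    )
    slots: list[tuple[tuple[int, int], tuple[int, int]]] = []  # (pt, direction)
    branch_points = []
    if n_side_branches:
        if len(slot_ys) < 2 * n_side_branches:
            raise ValueError("stem too short for the requested side branches")
        picks = np.linspace(0, len(slot_ys) - 1, n_side_branches + 2)[1:-1]
        used = set()
        for b, fidx in enumerate(picks):
            i = int(round(fidx))
            y = slot_ys[i]
            used.update((i - 1, i, i + 1))  # keep fruits off the attachment
            side = 1 if b % 2 == 0 else -1
            tip = (y - branch_len, x0 + side * branch_len)
            _thick_line(mask, (y, x0), tip)
            branch_points.append(((y, x0), tip, side))
        slot_ys = [y for i, y in enumerate(slot_ys) if i not in used]

    for i, y in enumerate(slot_ys):
        side = 1 if i % 2 == 0 else -1
        slots.append(((y, x0), (0, side)))
    for (ay, ax), (ty, tx), side in branch_points:
        # slots along the branch (45 degrees): stub points horizontally out
        nsteps = branch_len // _FRUIT_SPACING
        for k in range(2, nsteps):  # skip near the attachment
            py = ay - k * _FRUIT_SPACING
            px = ax + side * k * _FRUIT_SPACING
            slots.append(((py, px), (0, side)))

    if n_fruits > len(slots):
        raise ValueError(
            f"cannot place {n_fruits} fruits on {len(slots)} available slots; "
            "increase stem_len_px"
        )
    order = rng.permutation(len(slots))[:n_fruits]
    for idx in order:
        (py, px), (dy, dx) = slots[idx]
        tip = (py + dy * _FRUIT_LEN, px + dx * _FRUIT_LEN)
        _thick_line(mask, (py, px), tip)

    mask = dilation(mask, disk(_THICKNESS_RADIUS))
    truth = {
        "n_fruits": int(n_fruits),
        "n_side_branches": int(n_side_branches),
        "expected_triple_points": int(n_fruits + n_side_branches),
        "stem_len_px": int(stem_len_px),
        "mask": mask,
        "seed": seed,
    }
    return _paint(mask), truth


def gen_training_table(
    n: int,
    coefficients: dict[str, float],
    noise_cv: float = 0.05,
    predictor_ranges: dict[str, tuple[float, float]] | None = None,
    intercept: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Predictor/response table: predictors uniform on their ranges,
    response = (intercept + linear combination) * (1 + N(0, noise_cv))."""
    rng = np.random.default_rng(seed)
    if predictor_ranges is None:
        predictor_ranges = {k: (0.0, 1.0) for k in coefficients}
    data = {
        name: rng.uniform(lo, hi, size=n)
        for name, (lo, hi) in predictor_ranges.items()
    }
    df = pd.DataFrame(data)
    signal = intercept + sum(
        c * df[name].to_numpy() for name, c in coefficients.items()
    )
    noise = rng.normal(0.0, noise_cv, size=n) if noise_cv > 0 else 0.0
    df["response"] = signal * (1.0 + noise)
    truth = {
        "coefficients": dict(coefficients),
        "intercept": intercept,
        "noise_cv": noise_cv,
        "signal": signal,
        "seed": seed,
    }
    return df, truth


def gen_growth_series(
    A: float = 100.0,
    B: float = 4.0,
    t_inf: float = 20.0,
    days: np.ndarray | int = 30,
    noise_cv: float = 0.05,
    seed: int = 0,
    plant_id: str = "plant",
) -> tuple[MassSeries, dict]:
    """Logistic mass trajectory with multiplicative observation noise.

    ``days`` may be an int (days 1..days) or an explicit time vector.
    The final mass A is recorded exactly (it stands for the destructive
    measurement at maturity).
    """
    rng = np.random.default_rng(seed)
    t = (
        np.arange(1.0, days + 1.0)
        if np.isscalar(days)
        else np.asarray(days, dtype=float)
    )
    m_true = A / (1.0 + np.exp((t_inf - t) / B))
    noise = rng.normal(0.0, noise_cv, size=t.size) if noise_cv > 0 else 0.0
    m_obs = m_true * (1.0 + noise)
    series = MassSeries(
        plant_id=plant_id,
        times=t,
        masses=m_obs,
        A_final=A,
        maturity_day=float(t[-1]),
    )
    truth = {
        "A": A,
        "B": B,
        "t_inf": t_inf,
        "r": 1.0 / B,
        "noise_cv": noise_cv,
        "m_true": m_true,
        "seed": seed,
    }
    return series, truth


def gen_trait_table(
    n_genotypes: int = 200,
    n_reps: int = 2,
    sigma2_G: float = 1.0,
    sigma2_E: float = 1.0,
    mu: float = 10.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Genotype/replicate trait table from the one-way random-effects
    model: y_ik = mu + G_i + e_ik with the given variance components."""
    rng = np.random.default_rng(seed)
    g = rng.normal(0.0, np.sqrt(sigma2_G), size=n_genotypes)
    rows = []
    for i in range(n_genotypes):
        e = rng.normal(0.0, np.sqrt(sigma2_E), size=n_reps)
        for k in range(n_reps):
            rows.append(
                {
                    "genotype_id": f"g{i:04d}",
                    "replicate_id": k + 1,
                    "value": mu + g[i] + e[k],
                }
            )
    df = pd.DataFrame(rows)
    h2_true = (
        sigma2_G / (sigma2_G + sigma2_E) if (sigma2_G + sigma2_E) > 0 else 0.0
    )
    truth = {
        "sigma2_G": sigma2_G,
        "sigma2_E": sigma2_E,
        "H2": h2_true,
        "genotype_effects": g,
        "mu": mu,
        "seed": seed,
    }
    return df, truth
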