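"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately avoid the code paths they vet: boundary pixels
are enumerated by direct neighbourhood tests, the digitized perimeter is
summed along an angle-sorted boundary (valid for convex shapes), convex
hulls come from shapely rather than scipy, and Wilks' lambda is computed
through generalized eigenvalues instead of determinant ratios.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import seedmorph as sm
from seedmorph.morphometry import CSV_COLUMNS, FEATURE_NAMES


# ---------------------------------------------------------------- shapes

def digitized_disk(r: int, pad: int = 3) -> sm.SeedMask:
    """Mask of pixels whose centres lie within radius r of the origin."""
    yy, xx = np.mgrid[-r - pad: r + pad + 1, -r - pad: r + pad + 1]
    return sm.SeedMask(mask=(xx**2 + yy**2) <= r**2, specimen_id=f"disk_r{r}")


def digitized_ellipse(a: int, b: int, pad: int = 3) -> sm.SeedMask:
    yy, xx = np.mgrid[-b - pad: b + pad + 1, -a - pad: a + pad + 1]
    return sm.SeedMask(
        mask=(xx / a) ** 2 + (yy / b) ** 2 <= 1.0, specimen_id=f"ell_{a}x{b}"
    )


def filled_rectangle(w: int, h: int) -> sm.SeedMask:
    return sm.SeedMask(mask=np.ones((h, w), dtype=bool), specimen_id=f"rect_{w}x{h}")


# ---------------------------------------------------------------- oracles

def boundary_pixels_oracle(mask: np.ndarray) -> set[tuple[int, int]]:
    """Foreground pixels with a 4-neighbour outside the foreground."""
    m = np.asarray(mask, dtype=bool)
    out = set()
    H, W = m.shape
    for r, c in np.argwhere(m):
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if not (0 <= rr < H and 0 <= cc < W) or not m[rr, cc]:
                out.add((int(r), int(c)))
                break
    return out


def perimeter_oracle_convex(mask: np.ndarray) -> float:
    """Digitized perimeter of a convex mask, independent of Moore tracing:
    boundary pixels sorted by angle about the centroid, Euclidean steps."""
    pix = np.array(sorted(boundary_pixels_oracle(mask)), dtype=float)
    centroid = np.argwhere(mask).mean(axis=0)
    ang = np.arctan2(pix[:, 0] - centroid[0], pix[:, 1] - centroid[1])
    ordered = pix[np.argsort(ang)]
    return float(
        np.linalg.norm(np.roll(ordered, -1, axis=0) - ordered, axis=1).sum()
    )


def hull_oracle(points: np.ndarray) -> tuple[float, float]:
    """(perimeter, area) of the convex hull via shapely."""
    from shapely.geometry import MultiPoint

    hull = MultiPoint([tuple(p) for p in np.asarray(points, float)]).convex_hull
    return float(hull.length), float(hull.area)


def wilks_oracle(X: np.ndarray, y: np.ndarray, idx) -> float:
    """Wilks' lambda via generalized eigenvalues of (between, within)."""
    from scipy.linalg import eigh

    Xs = X[:, list(idx)]
    Xc = Xs - Xs.mean(axis=0)
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for c in np.unique(y):
        G = Xs[y == c]
        Gc = G - G.mean(axis=0)
        W += Gc.T @ Gc
    ev = eigh(T - W, W, eigvals_only=True)
    return float(np.prod(1.0 / (1.0 + np.clip(ev, 0.0, None))))


def gaussian_feature_table(
    rng: np.random.Generator,
    n_per_class: int,
    shift_per_feature: float,
    n_informative: int = 3,
    class_names: tuple[str, ...] = ("A", "B"),
) -> sm.FeatureTable:
    """Feature-space table: standard-normal noise on the 26 descriptor
    columns, with the first ``n_informative`` columns shifted per class."""
    rows = []
    for ci, name in enumerate(class_names):
        X = rng.normal(0.0, 1.0, (n_per_class, len(FEATURE_NAMES)))
        X[:, :n_informative] += ci * shift_per_feature
        for i in range(n_per_class):
            rows.append(
                {
                    "specimen_id": f"{name}{i}",
                    "class_label": name,
                    **{f: X[i, j] for j, f in enumerate(FEATURE_NAMES)},
                }
            )
    return sm.FeatureTable(data=pd.DataFrame(rows, columns=CSV_COLUMNS))


# ---------------------------------------------------------------- fixtures

SWEEP_SEED = 99


@pytest.fixture(scope="session")
def mask_sweep() -> sm.SyntheticPopulation:
    """1000 randomized seed-like masks: 20 heterogeneous shape classes
    spanning sizes 30-80 px, aspects 0.35-0.95, squareness 1.6-3.5 and
    boundary noise up to 4%."""
    rng = np.random.default_rng(2024)
    specs = [
        sm.ShapeClassSpec(
            name=f"c{i:02d}",
            size_px=(float(rng.uniform(30, 80)), 4.0),
            aspect=(float(rng.uniform(0.35, 0.95)), 0.04),
            squareness=(float(rng.uniform(1.6, 3.5)), 0.15),
            boundary_noise=float(rng.uniform(0.0, 0.04)),
            n=50,
        )
        for i in range(20)
    ]
    return sm.sample_population(specs, seed=SWEEP_SEED)


@pytest.fixture(scope="session")
def sweep_features(mask_sweep) -> sm.FeatureTable:
    return sm.extract_features(mask_sweep.masks)
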