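"""Shared fixtures and independent oracles for the test suite.

Oracles here are deliberately written from first principles (explicit loops,
brute-force search, direct enumeration) so they share no code path with the
implementation they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from pamvasc import synthetic_data as sd
from pamvasc import vessel_segmentation as vseg


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_phantom():
    """One branching vascular phantom with its ground truth."""
    return sd.generate_vessel_phantom(sd.VesselNetworkSpec(seed=7))


@pytest.fixture(scope="session")
def segmented_phantom(default_phantom):
    """(mask, skeleton, ground_truth) for the default phantom."""
    mip, gt = default_phantom
    mask = vseg.binarize(mip)
    skel = vseg.skeletonize(mask)
    return mask, skel, gt


@pytest.fixture(scope="session")
def rf_pulse_phantom():
    """Noise-free 40 MHz Gaussian-pulse phantom on an 8x8 grid."""
    spec = sd.RFPhantomSpec(
        seed=0,
        noise_sd=0.0,
        absorber_positions=tuple((i, j, 500) for i in range(8) for j in range(8)),
    )
    return spec, sd.generate_rf_phantom(spec)


@pytest.fixture(scope="session")
def separated_table():
    """Strongly separated (6 SD) two-class feature table, class sizes 10+30."""
    return sd.generate_feature_table((10, 30), effects=sd.default_effects(6.0), seed=0)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def nearest_background_sq_distance(mask: np.ndarray, r: int, c: int, window: int) -> int:
    """Exhaustive nearest-background search around (r, c).

    Scans every pixel of a (2*window+1)^2 neighborhood (clipped at the image
    border) and returns the minimal squared distance to a background pixel.
    Correct whenever the true nearest background lies inside the window,
    which callers must guarantee (window > reported distance).
    """
    rows, cols = mask.shape
    best = None
    for rr in range(max(0, r - window), min(rows, r + window + 1)):
        for cc in range(max(0, c - window), min(cols, c + window + 1)):
            if not mask[rr, cc]:
                d2 = (rr - r) ** 2 + (cc - c) ** 2
                if best is None or d2 < best:
                    best = d2
    assert best is not None, "no background pixel inside the search window"
    return best


def m_neighbors_oracle(skel: np.ndarray, r: int, c: int) -> list[tuple[int, int]]:
    """m-adjacent neighbors of (r, c), by explicit bounds-checked loops.

    Orthogonal skeleton neighbors always qualify; a diagonal neighbor
    qualifies only if neither pixel completing the corner is set.
    """
    rows, cols = skel.shape

    def on(rr, cc):
        return 0 <= rr < rows and 0 <= cc < cols and skel[rr, cc]

    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            if not on(r + dr, c + dc):
                continue
            if dr != 0 and dc != 0 and (on(r + dr, c) or on(r, c + dc)):
                continue
            out.append((r + dr, c + dc))
    return out


def classify_pixels_oracle(skel: np.ndarray):
    """Independent per-pixel m-neighbor counting.

    Returns (endpoint_pixels, branch_pixels, slab_pixels) as sets of (r, c);
    endpoints have <= 1 m-neighbor, slabs exactly 2, branch pixels >= 3.
    """
    rows, cols = skel.shape
    endpoints, branches, slabs = set(), set(), set()
    for r in range(rows):
        for c in range(cols):
            if not skel[r, c]:
                continue
            n = len(m_neighbors_oracle(skel, r, c))
            if n <= 1:
                endpoints.add((r, c))
            elif n == 2:
                slabs.add((r, c))
            else:
                branches.add((r, c))
    return endpoints, branches, slabs


def _flood_components(
    pixels: set[tuple[int, int]],
    skel: np.ndarray | None = None,
) -> list[set[tuple[int, int]]]:
    """Connected components of a pixel set by BFS.

    Plain 8-connectivity when ``skel`` is None; m-adjacency relative to the
    full skeleton otherwise (needed for slab components, where a redundant
    diagonal between two slab pixels is not a traversable step).
    """
    remaining = set(pixels)
    comps = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            r, c = frontier.pop()
            if skel is None:
                candidates = [
                    (r + dr, c + dc)
                    for dr in (-1, 0, 1)
                    for dc in (-1, 0, 1)
                    if not (dr == 0 and dc == 0)
                ]
            else:
                candidates = m_neighbors_oracle(skel, r, c)
            for q in candidates:
                if q in remaining:
                    remaining.remove(q)
                    comp.add(q)
                    frontier.append(q)
        comps.append(comp)
    return comps


def topology_counts_oracle(skel: np.ndarray) -> tuple[int, int, int]:
    """(n_endpoints, n_branch_nodes, n_segments) by flood fill + adjacency.

    Branch nodes are 8-connected clusters of branch pixels.  Segments are
    counted as connected components of the slab-pixel subgraph plus direct
    node-pixel adjacencies not mediated by any slab (which, after cluster
    merging, always involve at least one endpoint).
    """
    endpoints, branches, slabs = classify_pixels_oracle(skel)
    n_endpoints = len(endpoints)
    branch_clusters = _flood_components(branches)
    n_branch_nodes = len(branch_clusters)
    slab_components = _flood_components(slabs, skel=skel)
    node_pixels = endpoints | branches
    direct = set()
    for r, c in endpoints:
        for q in m_neighbors_oracle(skel, r, c):
            if q in node_pixels:
                direct.add(frozenset(((r, c), q)))
    return n_endpoints, n_branch_nodes, len(slab_components) + len(direct)


def welch_p_quadrature(t_stat: float, df: float) -> float:
    """Two-sided Welch p by numerical integration of the Student-t density."""
    from scipy.integrate import quad

    def density(x: float) -> float:
        return (
            math.gamma((df + 1) / 2)
            / (math.sqrt(df * math.pi) * math.gamma(df / 2))
            * (1 + x * x / df) ** (-(df + 1) / 2)
        )

    tail, _ = quad(density, abs(t_stat), np.inf)
    return 2.0 * tail


def auc_pair_counting(probs: np.ndarray, is_positive: np.ndarray) -> float:
    """AUC by enumerating every positive-negative pair; ties count half."""
    pos = probs[is_positive]
    neg = probs[~is_positive]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
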