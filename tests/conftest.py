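"""Shared fixtures and independent reference implementations (oracles)."""

from __future__ import annotations

import numpy as np
import pytest

from l3muscle import (
    ErrorProfile,
    generate_cohort,
    generate_phantom,
    simulate_model_mask,
)


# ---------------------------------------------------------------------------
# Oracles: deliberately naive, independent of the library code paths
# ---------------------------------------------------------------------------


def confusion_oracle(ref: np.ndarray, pred: np.ndarray) -> tuple[int, int, int]:
    """Per-pixel double-loop TP/FP/FN count."""
    tp = fp = fn = 0
    h, w = ref.shape
    for y in range(h):
        for x in range(w):
            r, p = bool(ref[y, x]), bool(pred[y, x])
            if r and p:
                tp += 1
            elif p:
                fp += 1
            elif r:
                fn += 1
    return tp, fp, fn


def dbscan_oracle(coords: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """Textbook O(n^2) DBSCAN: full distance matrix, BFS cluster expansion.

    Clusters are seeded scanning points in index order, so border pixels are
    claimed by the earliest-seeded reachable cluster.
    """
    n = len(coords)
    labels = np.full(n, -1, dtype=int)
    if n == 0:
        return labels
    c = coords.astype(float)
    d2 = ((c[:, None, :] - c[None, :, :]) ** 2).sum(-1)
    neigh = [np.flatnonzero(d2[i] <= eps * eps) for i in range(n)]
    core = np.array([len(nb) >= min_samples for nb in neigh])
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        labels[i] = cid
        queue = [i]
        while queue:
            j = queue.pop(0)
            for k in neigh[j]:
                if labels[k] == -1:
                    labels[k] = cid
                    if core[k]:
                        queue.append(int(k))
        cid += 1
    return labels


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration."""
    from math import comb

    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    probs = {}
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[aa] = comb(r1, aa) * comb(r2, c1 - aa) / denom
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)))


def random_blob_mask(rng: np.random.Generator, shape=(64, 64), n_blobs=3, density=0.0) -> np.ndarray:
    """Random mask built from a few rectangles plus optional salt noise."""
    mask = np.zeros(shape, dtype=bool)
    h, w = shape
    for _ in range(int(rng.integers(1, n_blobs + 1))):
        y0, x0 = rng.integers(0, h - 4), rng.integers(0, w - 4)
        dy, dx = rng.integers(2, 12), rng.integers(2, 12)
        mask[y0 : min(h, y0 + dy), x0 : min(w, x0 + dx)] = True
    if density > 0:
        mask |= rng.random(shape) < density
    return mask


@pytest.fixture(scope="session")
def default_cohort():
    """20 subjects with phantoms and default-error model masks (seeded)."""
    subjects = generate_cohort(20, seed=42)
    out = []
    for i, s in enumerate(subjects):
        ph = generate_phantom(s, seed=1000 + i)
        mask = simulate_model_mask(ph, ErrorProfile(), seed=2000 + i)
        out.append((ph, mask))
    return out


@pytest.fixture(scope="session")
def arms_down_phantom():
    subjects = [s for s in generate_cohort(40, seed=7) if s.arm_position == "down"]
    assert subjects, "seeded cohort should contain arms-down subjects"
    return generate_phantom(subjects[0], seed=77)
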