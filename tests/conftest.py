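import numpy as np
import pytest

from evapkmc import CellKind, InteractionParams, LatticeState


@pytest.fixture
def params():
    return InteractionParams()


def make_film(D=8, H=4, fill=CellKind.LIQUID, z=None):
    """A D x D x (H+1) state with substrate at layer 0 and uniform fill above."""
    grid = np.full((D, D, H + 1), fill, dtype=np.int8)
    grid[:, :, 0] = CellKind.SUBSTRATE
    return LatticeState(grid=grid, z=(H / D) if z is None else z)


def random_film(D, H, rng, p_particle=0.2, p_vapor=0.3):
    """Random liquid/vapor/particle film for oracle cross-checks."""
    fluid = rng.choice(
        [CellKind.LIQUID, CellKind.VAPOR, CellKind.PARTICLE],
        size=(D, D, H),
        p=[1 - p_particle - p_vapor, p_vapor, p_particle],
    ).astype(np.int8)
    grid = np.empty((D, D, H + 1), dtype=np.int8)
    grid[:, :, 0] = CellKind.SUBSTRATE
    grid[:, :, 1:] = fluid
    return LatticeState(grid=grid, z=H / D)


def flood_fill_label(mask, connectivity=8, periodic=False):
    """Brute-force BFS connected-component labeling (independent oracle)."""
    mask = np.asarray(mask, dtype=bool)
    n0, n1 = mask.shape
    if connectivity == 4:
        offs = [(0, 1), (0, -1), (1, 0), (-1, 0)]
    else:
        offs = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                if (di, dj) != (0, 0)]
    labels = np.zeros((n0, n1), dtype=np.int64)
    nxt = 0
    for i0 in range(n0):
        for j0 in range(n1):
            if not mask[i0, j0] or labels[i0, j0]:
                continue
            nxt += 1
            stack = [(i0, j0)]
            labels[i0, j0] = nxt
            while stack:
                i, j = stack.pop()
                for di, dj in offs:
                    ii, jj = i + di, j + dj
                    if periodic:
                        ii %= n0
                        jj %= n1
                    elif not (0 <= ii < n0 and 0 <= jj < n1):
                        continue
                    if mask[ii, jj] and not labels[ii, jj]:
                        labels[ii, jj] = nxt
                        stack.append((ii, jj))
    return labels, nxt


def partition_signature(labels):
    """Canonical form of a labeling: frozenset of frozensets of coordinates."""
    groups = {}
    for idx in zip(*np.nonzero(labels)):
        groups.setdefault(labels[idx], set()).add(idx)
    return frozenset(frozenset(g) for g in groups.values())
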