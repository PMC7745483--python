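"""Heterogeneous-network assembly and edge masking.

The network couples three relations in one symmetric block matrix::

    H = [[W_l, A  ],
         [A.T, W_m]]

with W_l the lncRNA similarity kNN graph (r x r), W_m the miRNA one (t x t),
and A the binary r x t interaction matrix.  Node order is fixed throughout
the package: lncRNAs first (input order), then miRNAs.
"""

from __future__ import annotations

import dataclasses

import numpy as np


@dataclasses.dataclass
class InteractionMatrix:
    """Known lncRNA-miRNA interactions as a binary r x t matrix."""

    A: np.ndarray
    lncrna_ids: list[str]
    mirna_ids: list[str]

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        r, t = self.A.shape
        if len(self.lncrna_ids) != r or len(self.mirna_ids) != t:
            raise ValueError("label lists do not match matrix shape")
        vals = np.unique(self.A)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("interaction matrix must be binary")

    @property
    def shape(self) -> tuple[int, int]:
        return self.A.shape

    def nnz(self) -> int:
        return int(self.A.sum())


@dataclasses.dataclass
class HeterogeneousNetwork:
    H: np.ndarray
    r: int
    t: int

    @property
    def n_nodes(self) -> int:
        return self.r + self.t


def assemble_hetnet(W_l: np.ndarray, A: InteractionMatrix | np.ndarray, W_m: np.ndarray) -> HeterogeneousNetwork:
    """Stack the two similarity graphs and the interaction matrix into H.

    Similarity blocks keep their real-valued weights; the interaction blocks
    carry unit weights — the blocks sit side by side without rescaling.
    """
    A_mat = A.A if isinstance(A, InteractionMatrix) else np.asarray(A)
    r, t = A_mat.shape
    W_l = np.asarray(W_l, dtype=float)
    W_m = np.asarray(W_m, dtype=float)
    if W_l.shape != (r, r):
        raise ValueError(f"W_l block is {W_l.shape}, expected ({r}, {r}) to match A with {r} lncRNAs")
    if W_m.shape != (t, t):
        raise ValueError(f"W_m block is {W_m.shape}, expected ({t}, {t}) to match A with {t} miRNAs")
    H = np.zeros((r + t, r + t))
    H[:r, :r] = W_l
    H[:r, r:] = A_mat
    H[r:, :r] = A_mat.T
    H[r:, r:] = W_m
    return HeterogeneousNetwork(H=H, r=r, t=t)


def disassemble_hetnet(net: HeterogeneousNetwork) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of :func:`assemble_hetnet`: returns (W_l, A, W_m) views."""
    r = net.r
    return net.H[:r, :r], net.H[:r, r:], net.H[r:, r:]


def mask_interactions(
    A: InteractionMatrix | np.ndarray,
    fraction: float,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Remove a uniformly random fraction of known interactions.

    Exactly ``round(fraction * nnz(A))`` ones are flipped to zero, chosen
    without replacement.  Returns the masked matrix and the removed (i, j)
    list, which cross-validation and the sparsity experiment use as held-out
    positives.
    """
    A_mat = (A.A if isinstance(A, InteractionMatrix) else np.asarray(A)).copy()
    if not (0 <= fraction < 1):
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    pos = np.argwhere(A_mat == 1)
    n_remove = int(round(fraction * len(pos)))
    if fraction > 0 and n_remove < 1:
        raise ValueError("fraction removes no edges; use fraction=0 for identity")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_remove == 0:
        return A_mat, []
    # a single permutation prefix makes removal sets nested across fractions
    # under a common seed (couples the sparsity grid without changing the
    # uniform-without-replacement marginal)
    chosen = pos[rng.permutation(len(pos))[:n_remove]]
    A_mat[chosen[:, 0], chosen[:, 1]] = 0
    return A_mat, [tuple(int(v) for v in ij) for ij in chosen]
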