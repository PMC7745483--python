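"""Synthetic sequence and interaction data with planted block structure.

Real lncRNA-miRNA interaction data couple two signals: sequence similarity
(similar lncRNAs tend to bind similar miRNAs) and network topology (groups of
entities co-interact).  The generator plants both at a controllable strength:
entities are partitioned into blocks, each block derives its sequences by
point-mutating a shared random ancestor, and interactions are drawn
Bernoulli(within_block_link_prob) inside a block pairing and
Bernoulli(cross_block_link_prob) outside it.  With mutation_rate small and
within >> cross, k-mer similarity is informative for links — the assumption
the heterogeneous-network construction exploits.

Everything is deterministic given ``spec.seed``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .hetnet import InteractionMatrix

RNA_ALPHABET = "ACGU"


@dataclasses.dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Parameters of the planted-structure generator.

    The default sizes are a desk-scale analogue of a compiled interaction
    catalogue (hundreds of lncRNAs by hundreds of miRNAs): 60 lncRNA-like
    sequences of 200-400 nt, 30 miRNA-like sequences of 20-25 nt, three
    co-interacting blocks, dense links within a block pairing and sparse
    links across.
    """

    n_lncrna: int = 60
    n_mirna: int = 30
    n_blocks: int = 3
    lncrna_len_range: tuple[int, int] = (200, 400)
    mirna_len_range: tuple[int, int] = (20, 25)
    within_block_link_prob: float = 0.5
    cross_block_link_prob: float = 0.02
    mutation_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.cross_block_link_prob < self.within_block_link_prob <= 1):
            raise ValueError(
                "require 0 <= cross_block_link_prob < within_block_link_prob <= 1, "
                f"got cross={self.cross_block_link_prob}, within={self.within_block_link_prob}"
            )
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be positive")
        if self.n_lncrna < self.n_blocks or self.n_mirna < self.n_blocks:
            raise ValueError("need at least one entity of each kind per block")
        if not (0 <= self.mutation_rate <= 1):
            raise ValueError("mutation_rate must be a probability")
        for lo, hi in (self.lncrna_len_range, self.mirna_len_range):
            if not (0 < lo <= hi):
                raise ValueError("length ranges must satisfy 0 < lo <= hi")


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    id: str
    kind: str  # "lncRNA" | "miRNA"
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for {self.id}")


def _block_assignment(n: int, n_blocks: int) -> np.ndarray:
    # round-robin keeps every block populated even when n_blocks ∤ n
    return np.arange(n) % n_blocks


def _mutate(ancestor: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitution-only point mutation: each site independently resampled
    (to a different base) with probability ``rate``."""
    seq = ancestor.copy()
    hits = rng.random(seq.size) < rate
    if hits.any():
        # draw from the 3 alternative bases
        offsets = rng.integers(1, 4, size=int(hits.sum()))
        seq[hits] = (seq[hits] + offsets) % 4
    return seq


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(RNA_ALPHABET[c] for c in codes)


def generate_sequences(spec: SyntheticDatasetSpec, min_length: int = 5) -> tuple[list[SequenceRecord], dict]:
    """Generate block-structured sequences for both entity kinds.

    Each block has an i.i.d.-uniform ancestor sequence; members are
    point-mutated copies, so intra-block k-spectrum similarity exceeds
    inter-block similarity in expectation.

    Returns (records, block_assignment) where block_assignment maps
    ``"lncRNA"``/``"miRNA"`` to an integer block label per entity.

    ``min_length`` guards the downstream spectrum featurizer: a length range
    whose lower bound is below the spectrum k is rejected here.
    """
    for label, (lo, _hi) in (("lncRNA", spec.lncrna_len_range), ("miRNA", spec.mirna_len_range)):
        if lo < min_length:
            raise ValueError(
                f"{label} length lower bound {lo} is below the spectrum k-mer size {min_length}"
            )
    rng = np.random.default_rng(spec.seed)
    records: list[SequenceRecord] = []
    blocks: dict[str, list[int]] = {}
    for kind, prefix, n, len_range in (
        ("lncRNA", "lnc", spec.n_lncrna, spec.lncrna_len_range),
        ("miRNA", "mir", spec.n_mirna, spec.mirna_len_range),
    ):
        assign = _block_assignment(n, spec.n_blocks)
        blocks[kind] = assign.tolist()
        # one ancestor per block, drawn at the top of the range so mutated
        # copies can be truncated to their own sampled length
        ancestors = [rng.integers(0, 4, size=len_range[1]) for _ in range(spec.n_blocks)]
        lengths = rng.integers(len_range[0], len_range[1] + 1, size=n)
        for i in range(n):
            codes = _mutate(ancestors[assign[i]], spec.mutation_rate, rng)[: lengths[i]]
            records.append(SequenceRecord(id=f"{prefix}{i:04d}", kind=kind, residues=_codes_to_str(codes)))
    return records, blocks


def generate_interactions(spec: SyntheticDatasetSpec, block_assignment: dict) -> InteractionMatrix:
    """Draw the bipartite interaction matrix from the planted block model.

    A(i,j) ~ Bernoulli(within) if lncRNA i and miRNA j share a block, else
    Bernoulli(cross).  Uses a seed stream distinct from the sequence stream
    so sequences and links are conditionally independent given blocks.
    """
    lnc_blocks = np.asarray(block_assignment["lncRNA"])
    mir_blocks = np.asarray(block_assignment["miRNA"])
    r, t = lnc_blocks.size, mir_blocks.size
    rng = np.random.default_rng(spec.seed + 1_000_003)
    same = lnc_blocks[:, None] == mir_blocks[None, :]
    prob = np.where(same, spec.within_block_link_prob, spec.cross_block_link_prob)
    A = (rng.random((r, t)) < prob).astype(np.int8)
    return InteractionMatrix(
        A=A,
        lncrna_ids=[f"lnc{i:04d}" for i in range(r)],
        mirna_ids=[f"mir{j:04d}" for j in range(t)],
    )


def generate_dataset(spec: SyntheticDatasetSpec, min_length: int = 5):
    """Sequences + interactions in one call.

    Returns (records, interactions, block_assignment).
    """
    records, blocks = generate_sequences(spec, min_length=min_length)
    inter = generate_interactions(spec, blocks)
    return records, inter, blocks


# ---------------------------------------------------------------- file output

def write_dataset(outdir: str | Path, records, interactions: InteractionMatrix, blocks, spec) -> dict:
    """Write FASTA per kind, a TSV edge list and a JSON sidecar of the spec
    and block assignment (the test oracle needs the planted truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "lncrna_fasta": outdir / "lncrna.fasta",
        "mirna_fasta": outdir / "mirna.fasta",
        "interactions": outdir / "interactions.tsv",
        "sidecar": outdir / "dataset.json",
    }
    by_kind = {"lncRNA": [], "miRNA": []}
    for rec in records:
        by_kind[rec.kind].append(rec)
    for kind, path_key in (("lncRNA", "lncrna_fasta"), ("miRNA", "mirna_fasta")):
        with open(paths[path_key], "w") as fh:
            for rec in by_kind[kind]:
                fh.write(f">{rec.id}\n{rec.residues}\n")
    with open(paths["interactions"], "w") as fh:
        for i, j in zip(*np.nonzero(interactions.A)):
            fh.write(f"{interactions.lncrna_ids[i]}\t{interactions.mirna_ids[j]}\n")
    with open(paths["sidecar"], "w") as fh:
        json.dump(
            {"spec": dataclasses.asdict(spec), "block_assignment": blocks},
            fh,
            indent=2,
            default=list,
        )
    return {k: str(v) for k, v in paths.items()}
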