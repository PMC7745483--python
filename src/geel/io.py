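"""File I/O and pipeline configuration.

Sequences come in as FASTA (DNA is normalized to the internal RNA alphabet:
T -> U, case-folded to upper), interactions as a two-column TSV edge list of
``lncrna_id<TAB>mirna_id``.  Matrices travel as dense TSV or MatrixMarket
MTX with a row-label sidecar; reports as TSV/JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO

from .fixtures import SequenceRecord
from .hetnet import InteractionMatrix

_VALID = set("ACGU")


def read_fasta(path: str | Path, kind: str = "lncRNA") -> list[SequenceRecord]:
    """Read sequences; ids are header tokens up to the first whitespace.

    Normalization: upper-case, T -> U.  Duplicate ids, empty sequences or
    non-ACGU residues raise with the offending ids listed.
    """
    records = []
    seen: set[str] = set()
    bad: dict[str, list[str]] = {"duplicate": [], "empty": [], "alphabet": []}
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper().replace("T", "U")
        if rec.id in seen:
            bad["duplicate"].append(rec.id)
            continue
        seen.add(rec.id)
        if not residues:
            bad["empty"].append(rec.id)
            continue
        if set(residues) - _VALID:
            bad["alphabet"].append(rec.id)
            continue
        records.append(SequenceRecord(id=rec.id, kind=kind, residues=residues))
    problems = {k: v for k, v in bad.items() if v}
    if problems:
        raise ValueError(f"invalid FASTA records in {path}: {problems}")
    if not records:
        warnings.warn(f"no sequences found in {path}")
    return records


def write_fasta(path: str | Path, records) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.residues}\n")


def read_interactions(path: str | Path, lncrna_ids, mirna_ids) -> InteractionMatrix:
    """Parse the edge list into the binary interaction matrix.

    Duplicate edges are collapsed (count reported), edges referencing
    unknown ids are rejected with a report; the matrix is ordered by the
    FASTA id order.  Zero surviving edges is an error.
    """
    lnc_index = {x: i for i, x in enumerate(lncrna_ids)}
    mir_index = {x: j for j, x in enumerate(mirna_ids)}
    A = np.zeros((len(lncrna_ids), len(mirna_ids)), dtype=np.int8)
    n_dup = 0
    rejected = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                rejected.append((line_no, line, "not two columns"))
                continue
            l_id, m_id = parts
            if l_id not in lnc_index or m_id not in mir_index:
                rejected.append((line_no, line, "unknown id"))
                continue
            i, j = lnc_index[l_id], mir_index[m_id]
            if A[i, j]:
                n_dup += 1
            A[i, j] = 1
    if rejected:
        warnings.warn(f"{path}: rejected {len(rejected)} edges: {rejected[:10]}")
    if n_dup:
        warnings.warn(f"{path}: collapsed {n_dup} duplicate edges")
    if A.sum() == 0:
        raise ValueError(f"{path}: no valid interactions survive parsing")
    return InteractionMatrix(A=A, lncrna_ids=list(lncrna_ids), mirna_ids=list(mirna_ids))


def write_matrix_tsv(path: str | Path, M: np.ndarray, row_labels=None) -> None:
    with open(path, "w") as fh:
        for i, row in enumerate(np.asarray(M)):
            label = f"{row_labels[i]}\t" if row_labels is not None else ""
            fh.write(label + "\t".join(f"{v:.10g}" for v in row) + "\n")


def write_scores_tsv(path: str | Path, pairs, scores, lncrna_ids, mirna_ids) -> None:
    with open(path, "w") as fh:
        fh.write("lncrna_id\tmirna_id\tscore\n")
        for (i, j), s in zip(np.asarray(pairs), scores):
            fh.write(f"{lncrna_ids[i]}\t{mirna_ids[j]}\t{s:.6f}\n")


@dataclasses.dataclass
class PipelineConfig:
    """Everything the end-to-end run needs, YAML round-trippable."""

    lncrna_fasta: str = ""
    mirna_fasta: str = ""
    interactions: str = ""
    outdir: str = "geel_out"
    k: int = 5
    kappa: int = 10
    n_neighbors: int = 10
    n_components: int | None = None  # None -> per-method defaults of the chosen scale
    embed_overrides: dict = dataclasses.field(default_factory=dict)
    head: str = "geel-pi"  # geel-pi | geel-fi | geel-f
    views: tuple = ("GraRep", "LE")
    pair_dim: int = 160
    n_estimators_fi: int = 2000
    n_folds: int = 5
    repeats: int = 1
    folds_evaluated: int | None = None
    sparsity_ratios: tuple = (0.1, 0.2, 0.3, 0.4)
    threshold: float = 0.5
    seed: int = 0
    scale: str = "fixture"  # embedding preset: fixture | full

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for tup in ("views", "sparsity_ratios"):
            if tup in raw and raw[tup] is not None:
                raw[tup] = tuple(raw[tup])
        return cls(**raw)

    def semantic_hash(self) -> str:
        """Hash of the fields that determine results (output location excluded)."""
        fields = dataclasses.asdict(self)
        fields.pop("outdir")
        payload = json.dumps(fields, sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
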