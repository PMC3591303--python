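"""Seeded synthetic protein data for testing and benchmarking.

All generators are pure functions of their seeds: the same seed always
produces the same sequences.  The default residue composition is uniform
over the 20 standard amino acids; a Robinson-style natural composition is
available for statistics-sensitive fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SequenceRecord
from .postprocess import ROBINSON_FREQUENCIES

#: Residue order used by the generators (NCBI matrix header order).
RESIDUES = "ARNDCQEGHILKMFPSTWYV"


def _composition(kind: str) -> np.ndarray:
    if kind == "uniform":
        return np.full(20, 1.0 / 20.0)
    if kind == "robinson":
        p = np.array([ROBINSON_FREQUENCIES[c] for c in RESIDUES])
        return p / p.sum()
    raise ValueError(f"unknown composition '{kind}'")


def random_protein(length: int, rng: np.random.Generator, composition="uniform") -> str:
    p = _composition(composition) if isinstance(composition, str) else composition
    idx = rng.choice(20, size=length, p=p)
    return "".join(RESIDUES[i] for i in idx)


def random_proteome(
    n_seqs: int,
    length=300,
    seed: int = 0,
    composition: str = "uniform",
    prefix: str = "seq",
) -> list[SequenceRecord]:
    """n_seqs i.i.d. random proteins.  ``length`` is either a fixed integer
    or a ``(lo, hi)`` range sampled uniformly per sequence."""
    if n_seqs < 1:
        raise ValueError("n_seqs must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_seqs):
        if isinstance(length, tuple):
            ln = int(rng.integers(length[0], length[1] + 1))
        else:
            ln = int(length)
        out.append(SequenceRecord(id=f"{prefix}{i}", seq=random_protein(ln, rng, composition)))
    return out


@dataclass
class MutationModel:
    """Per-residue substitution and indel process for homolog simulation.

    Indel lengths are geometric with the given mean.  ``n_insertions`` /
    ``n_deletions`` place an exact number of indels at random positions
    instead of the per-residue rates when set.
    """

    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    mean_indel_len: float = 3.0
    n_insertions: int | None = None
    n_deletions: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.insertion_rate, self.deletion_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError("rates must be in [0, 1)")


def _geom_len(rng: np.random.Generator, mean: float) -> int:
    return int(rng.geometric(1.0 / max(mean, 1.0)))


def mutate_homolog(
    seq: str, model: MutationModel, composition: str = "uniform"
) -> tuple[str, list[tuple[str, int]]]:
    """Mutated copy of ``seq`` plus the ground-truth alignment path.

    The path is a run-length op list over (original, mutant): ``M`` aligned
    column, ``D`` original residue deleted, ``I`` residue inserted in the
    mutant.  Replaying the path on the pair reconstructs the mutant.
    """
    rng = np.random.default_rng(model.seed)
    p = _composition(composition)
    n = len(seq)

    # substitution step (always to a different residue)
    residues = list(seq)
    sub_mask = rng.random(n) < model.substitution_rate
    for i in np.nonzero(sub_mask)[0]:
        choices = [c for c in RESIDUES if c != residues[i]]
        residues[i] = choices[int(rng.integers(len(choices)))]

    # indel placement
    if model.n_deletions is not None:
        del_starts = sorted(rng.choice(n, size=model.n_deletions, replace=False))
    else:
        del_starts = sorted(np.nonzero(rng.random(n) < model.deletion_rate)[0])
    if model.n_insertions is not None:
        ins_points = sorted(rng.choice(n + 1, size=model.n_insertions, replace=False))
    else:
        ins_points = sorted(np.nonzero(rng.random(n + 1) < model.insertion_rate)[0])

    deletions: dict[int, int] = {}
    cursor = 0
    for st in del_starts:
        if st < cursor:
            continue
        ln = min(_geom_len(rng, model.mean_indel_len), n - st)
        deletions[int(st)] = ln
        cursor = st + ln
    insertions = {
        int(pt): random_protein(_geom_len(rng, model.mean_indel_len), rng, p)
        for pt in ins_points
    }

    mutant: list[str] = []
    ops: list[str] = []
    i = 0
    while i <= n:
        if i in insertions:
            mutant.append(insertions[i])
            ops.extend("I" * len(insertions[i]))
        if i == n:
            break
        if i in deletions:
            ln = deletions[i]
            ops.extend("D" * ln)
            i += ln
            continue
        mutant.append(residues[i])
        ops.append("M")
        i += 1

    from itertools import groupby

    path = [(op, sum(1 for _ in g)) for op, g in groupby(ops)]
    return "".join(mutant), path


def replay_path(original: str, mutant: str, path) -> bool:
    """Check that the truth path is consistent with the sequence pair."""
    oi = mi = 0
    for op, ln in path:
        if op == "M":
            oi += ln
            mi += ln
        elif op == "D":
            oi += ln
        else:
            mi += ln
    return oi == len(original) and mi == len(mutant)


def make_repeat_protein(
    unit: str, copies: int, spacer_len: int, seed: int = 0
) -> tuple[str, list[tuple[int, int]]]:
    """Protein of ``copies`` tandem copies of ``unit`` separated by random
    spacers; returns the sequence and the (start, end) of each copy."""
    if copies < 2:
        raise ValueError("copies must be >= 2")
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    coords: list[tuple[int, int]] = []
    pos = 0
    for c in range(copies):
        parts.append(unit)
        coords.append((pos, pos + len(unit)))
        pos += len(unit)
        if c < copies - 1:
            parts.append(random_protein(spacer_len, rng))
            pos += spacer_len
    return "".join(parts), coords


def make_fusion_protein(
    domain_a: str, domain_b: str, linker_len: int, seed: int = 0
) -> tuple[str, list[tuple[int, int]]]:
    """Two-domain fusion with a random linker; returns sequence and the
    (start, end) of each domain."""
    rng = np.random.default_rng(seed)
    linker = random_protein(linker_len, rng)
    seq = domain_a + linker + domain_b
    coords = [
        (0, len(domain_a)),
        (len(domain_a) + linker_len, len(seq)),
    ]
    return seq, coords


def planted_homolog_trial(
    seed: int,
    query_len: int = 300,
    n_decoys: int = 50,
    substitution_rate: float = 0.2,
    n_insertions: int = 1,
    n_deletions: int = 1,
) -> tuple[SequenceRecord, list[SequenceRecord], str]:
    """One planted-homolog search instance: a random query, its mutated copy
    hidden among random decoys (shuffled order).  Returns (query record,
    subject records, id of the planted homolog)."""
    rng = np.random.default_rng(seed)
    query = SequenceRecord(id="query0", seq=random_protein(query_len, rng))
    model = MutationModel(
        substitution_rate=substitution_rate,
        n_insertions=n_insertions,
        n_deletions=n_deletions,
        seed=int(rng.integers(2**31 - 1)),
    )
    homolog_seq, _ = mutate_homolog(query.seq, model)
    subjects = [
        SequenceRecord(id=f"decoy{i}", seq=random_protein(query_len, rng))
        for i in range(n_decoys)
    ]
    subjects.append(SequenceRecord(id="planted", seq=homolog_seq))
    order = rng.permutation(len(subjects))
    subjects = [subjects[i] for i in order]
    return query, subjects, "planted"
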