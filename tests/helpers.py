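"""Independent oracles and fixture builders shared across the test suite.

The oracles are deliberately written as plain loops over reads, contigs and
offsets — slow but unmistakably correct — and never call into the matching
implementation they are used to audit.
"""

from __future__ import annotations

import numpy as np

from cqcov.matching import ContigSet, ReadSet, decode, revcomp


# ---------------------------------------------------------------------------
# brute-force matching oracles
# ---------------------------------------------------------------------------


def brute_exact_counts(reads: ReadSet, contigs: ContigSet,
                       both_strands: bool = True) -> dict[str, int]:
    """Count zero-mismatch placements by scanning every offset of every contig."""
    tallies = {n: 0 for n in contigs.names}
    for row in reads.codes:
        probes = [row]
        if both_strands:
            probes.append(revcomp(row))
        for probe in probes:
            L = probe.size
            for name, seq in zip(contigs.names, contigs.seqs):
                for d in range(seq.size - L + 1):
                    window = seq[d : d + L]
                    if np.all((window == probe) & (window < 4) & (probe < 4)):
                        tallies[name] += 1
    return tallies


def brute_ident_counts(reads: ReadSet, contigs: ContigSet,
                       min_identity: float = 0.8,
                       both_strands: bool = True) -> dict[str, int]:
    """Best ungapped full-length placement per read, by exhaustive scan.

    Ties go to the lowest contig name, then lowest offset, then forward
    strand — the documented tie-break order.
    """
    L = reads.read_length
    budget = int(np.floor((1 - min_identity) * L + 1e-9))
    name_rank = {n: r for r, n in enumerate(sorted(contigs.names))}
    tallies = {n: 0 for n in contigs.names}
    for row in reads.codes:
        strands = [(0, row)] + ([(1, revcomp(row))] if both_strands else [])
        best = None
        for strand, probe in strands:
            for name, seq in zip(contigs.names, contigs.seqs):
                for d in range(seq.size - L + 1):
                    window = seq[d : d + L]
                    matches = (window == probe) & (window < 4) & (probe < 4)
                    mm = L - int(matches.sum())
                    if mm <= budget:
                        key = (mm, name_rank[name], d, strand)
                        if best is None or key < best[0]:
                            best = (key, name)
        if best is not None:
            tallies[best[1]] += 1
    return tallies


# ---------------------------------------------------------------------------
# fixture builders
# ---------------------------------------------------------------------------


def random_contigs(rng: np.random.Generator, n: int, length: int,
                   with_n: bool = False, prefix: str = "c") -> ContigSet:
    names, seqs = [], []
    for i in range(n):
        codes = rng.integers(0, 4, size=length).astype(np.uint8)
        if with_n:
            codes[rng.integers(length)] = 4  # one N per contig
        names.append(f"{prefix}{i}")
        seqs.append(codes)
    return ContigSet(names, seqs)


def planted_reads(rng: np.random.Generator, contigs: ContigSet, n: int,
                  read_length: int, max_mut: int = 25,
                  sample_id: str = "fixture") -> ReadSet:
    """Reads drawn from the contigs (mutated, either strand) plus decoys."""
    seqs = []
    for _ in range(n):
        kind = rng.integers(4)
        if kind == 3:  # unrelated decoy
            codes = rng.integers(0, 4, size=read_length).astype(np.uint8)
        else:
            ci = rng.integers(len(contigs))
            seq = contigs.seqs[ci]
            d = rng.integers(seq.size - read_length + 1)
            codes = seq[d : d + read_length].copy()
            if kind == 1:
                nmut = int(rng.integers(0, max_mut + 1))
                pos = rng.choice(read_length, size=nmut, replace=False)
                codes[pos] = (codes[pos] + rng.integers(1, 4, size=nmut)) % 4
            elif kind == 2:
                codes = revcomp(codes)
        seqs.append(decode(codes))
    return ReadSet.from_sequences(seqs, sample_id=sample_id)


# ---------------------------------------------------------------------------
# median-of-ratios reference (formula followed step by step)
# ---------------------------------------------------------------------------


def size_factors_reference(matrix) -> list[float]:
    """Median-of-ratios factors computed with explicit loops, geomean 1."""
    values = matrix.to_numpy(dtype=float)
    n_contigs, n_samples = values.shape
    ratios: list[list[float]] = [[] for _ in range(n_samples)]
    for i in range(n_contigs):
        if all(values[i, j] > 0 for j in range(n_samples)):
            geo = float(np.prod(values[i]) ** (1.0 / n_samples))
            for j in range(n_samples):
                ratios[j].append(values[i, j] / geo)
    raw = [float(np.median(r)) for r in ratios]
    geo = float(np.prod(raw) ** (1.0 / n_samples))
    return [r / geo for r in raw]
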