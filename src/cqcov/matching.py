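"""Stringent whole-read alignment counting against contig sets.

Two matching regimes drive the downstream statistics:

``EXACT``
    every (read, offset, strand) placement at which the full read equals the
    contig substring with zero mismatches is counted.  A read hitting several
    contigs (or several offsets) contributes one alignment per placement.
    This is the regime behind the chromosome quotient, where multi-counting
    of repetitive placements is intentional.

``IDENT80``
    ungapped, full-length placement with a mismatch budget of
    ``floor((1 - min_identity) * read_length)``.  Each read is assigned to its
    single best placement (fewest mismatches; ties broken by contig name,
    then offset, then forward strand), so the resulting counts can be turned
    into per-contig depth without inflation.

Both counters are vectorised: contigs are concatenated with a sentinel byte,
window fingerprints are computed with an invertible 64-bit rolling hash, and
every candidate placement is verified against the actual sequence, so hash
collisions cannot leak into the counts.  ``N`` never matches anything, in
either role.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

log = logging.getLogger(__name__)

EXACT = "EXACT"
IDENT80 = "IDENT80"

# ---------------------------------------------------------------------------
# sequence encoding
# ---------------------------------------------------------------------------

A, C, G, T, N = 0, 1, 2, 3, 4
_SEP = 5        # sentinel between concatenated contigs; never equals a read base
_READ_N = 6     # N inside a read; never equals any genome code (N is a mismatch)

_ENC = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i  # lower case
_DEC = np.frombuffer(b"ACGTN-N", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0,C=1,G=2,T=3, other=N)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of a code vector; N maps to N."""
    out = codes[::-1].copy()
    m = out < 4
    out[m] = 3 - out[m]
    return out


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


class ContigSet:
    """An ordered, named collection of contig sequences (uint8-coded)."""

    def __init__(self, names: list[str], seqs: list[np.ndarray]):
        if len(names) != len(seqs):
            raise ValueError("names and sequences differ in length")
        if len(set(names)) != len(names):
            raise ValueError("duplicate contig names")
        for name, s in zip(names, seqs):
            if s.size == 0:
                raise ValueError(f"zero-length contig {name!r}")
        self.names = list(names)
        self.seqs = [np.asarray(s, dtype=np.uint8) for s in seqs]
        self.lengths = np.array([s.size for s in self.seqs], dtype=np.int64)
        self._index = {n: i for i, n in enumerate(self.names)}

    # -- construction -------------------------------------------------
    @classmethod
    def from_records(cls, records: dict[str, str]) -> "ContigSet":
        return cls(list(records), [encode(s) for s in records.values()])

    @classmethod
    def from_fasta(cls, path) -> "ContigSet":
        names, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            names.append(rec.id)
            seqs.append(encode(str(rec.seq)))
        if not names:
            raise ValueError(f"no sequences in {path}")
        return cls(names, seqs)

    # -- access -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def sequence(self, name: str) -> str:
        return decode(self.seqs[self._index[name]])

    @property
    def total_bases(self) -> int:
        return int(self.lengths.sum())

    def subset(self, names) -> "ContigSet":
        idx = [self._index[n] for n in names]
        return ContigSet([self.names[i] for i in idx], [self.seqs[i] for i in idx])

    def reverse_complemented(self) -> "ContigSet":
        return ContigSet(list(self.names), [revcomp(s) for s in self.seqs])

    # -- io -----------------------------------------------------------
    def to_fasta(self, path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, s in zip(self.names, self.seqs):
                fh.write(f">{name}\n")
                text = decode(s)
                for i in range(0, len(text), width):
                    fh.write(text[i : i + width] + "\n")


class ReadSet:
    """A fixed-length read library as an (n_reads, read_length) code matrix.

    The matrix keeps ``N`` as code 4; the matching routines remap it so that
    an ``N`` never matches any reference base (including a reference ``N``).
    """

    def __init__(self, codes: np.ndarray, names: list[str] | None = None,
                 sample_id: str = "sample"):
        codes = np.asarray(codes, dtype=np.uint8)
        if codes.ndim != 2:
            raise ValueError("read codes must be a 2-D matrix")
        if names is not None and len(names) != codes.shape[0]:
            raise ValueError("read names and matrix rows differ")
        self.codes = codes
        self.names = names
        self.sample_id = sample_id

    @property
    def n_reads(self) -> int:
        return self.codes.shape[0]

    @property
    def read_length(self) -> int:
        return self.codes.shape[1]

    @classmethod
    def from_sequences(cls, seqs: list[str], names: list[str] | None = None,
                       sample_id: str = "sample") -> "ReadSet":
        if not seqs:
            raise ValueError("empty read set")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("reads must share a single length")
        mat = np.vstack([encode(s) for s in seqs])
        return cls(mat, names, sample_id)

    @classmethod
    def from_fastq(cls, path, sample_id: str | None = None) -> "ReadSet":
        names, seqs = [], []
        with open(path) as fh:
            for name, seq, _qual in FastqGeneralIterator(fh):
                names.append(name.split()[0])
                seqs.append(seq)
        if not seqs:
            raise ValueError(f"no reads in {path}")
        return cls.from_sequences(seqs, names,
                                  sample_id or Path(path).stem)

    def to_fastq(self, path) -> None:
        qual = "I" * self.read_length  # constant Phred+33 quality 40
        names = self.names or [f"{self.sample_id}.{i}" for i in range(self.n_reads)]
        with open(path, "w") as fh:
            for name, row in zip(names, self.codes):
                fh.write(f"@{name}\n{decode(row)}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# rolling-hash machinery
# ---------------------------------------------------------------------------

_BASE = np.uint64(0x9E3779B97F4A7C15)                      # odd => invertible mod 2^64
_BASE_INV = np.uint64(pow(0x9E3779B97F4A7C15, -1, 1 << 64))


def _powers(n: int, base: np.uint64) -> np.ndarray:
    """base**j mod 2^64 for j = 0..n-1 (uint64 wrap-around is the modulus)."""
    pw = np.full(n, base, dtype=np.uint64)
    if n:
        pw[0] = 1
    return np.cumprod(pw, dtype=np.uint64)


def _window_hashes(cat: np.ndarray, L: int) -> np.ndarray:
    """Hash of every length-L window of `cat`: H[d] = sum_i cat[d+i] * base^i."""
    n = cat.size
    if n < L:
        return np.empty(0, dtype=np.uint64)
    pw = _powers(n, _BASE)
    pwinv = _powers(n - L + 1, _BASE_INV)
    t = np.zeros(n + 1, dtype=np.uint64)
    np.cumsum(cat.astype(np.uint64) * pw, out=t[1:])
    return (t[L:] - t[:-L]) * pwinv


def _row_hashes(codes: np.ndarray, pw: np.ndarray) -> np.ndarray:
    """Per-row hash of a code matrix under the same fingerprint as windows."""
    h = np.zeros(codes.shape[0], dtype=np.uint64)
    for i in range(codes.shape[1]):
        h += codes[:, i].astype(np.uint64) * pw[i]
    return h


def _expand_ranges(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expand per-query [lo, hi) index ranges into (query_idx, flat_idx) pairs."""
    cnt = (hi - lo).astype(np.int64)
    total = int(cnt.sum())
    if total == 0:
        return (np.empty(0, dtype=np.int64),) * 2
    qidx = np.repeat(np.arange(lo.size, dtype=np.int64), cnt)
    cs = np.cumsum(cnt)
    offs = np.arange(total, dtype=np.int64) - np.repeat(cs - cnt, cnt)
    return qidx, np.repeat(lo.astype(np.int64), cnt) + offs


class _Genome:
    """Contigs concatenated with sentinel separators, plus bookkeeping."""

    def __init__(self, contigs: ContigSet):
        self.contigs = contigs
        parts: list[np.ndarray] = []
        starts = np.empty(len(contigs), dtype=np.int64)
        pos = 0
        sep = np.array([_SEP], dtype=np.uint8)
        for i, s in enumerate(contigs.seqs):
            if i:
                parts.append(sep)
                pos += 1
            starts[i] = pos
            parts.append(s)
            pos += s.size
        self.cat = np.concatenate(parts) if parts else np.empty(0, np.uint8)
        self.starts = starts
        self.ends = starts + contigs.lengths
        # rank of each contig under lexicographic name order (tie-breaking)
        order = sorted(range(len(contigs)), key=lambda i: contigs.names[i])
        self.name_rank = np.empty(len(contigs), dtype=np.int64)
        self.name_rank[order] = np.arange(len(contigs))

    def contig_of(self, pos: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.starts, pos, side="right") - 1


# ---------------------------------------------------------------------------
# alignment count container
# ---------------------------------------------------------------------------


@dataclass
class AlignmentCounts:
    """Per-contig alignment tallies for one sample under one regime."""

    sample_id: str
    regime: str
    counts: pd.Series            # contig name -> number of alignments
    lengths: pd.Series           # contig name -> contig length (bp)
    library_total_reads: int
    read_length: int
    min_identity: float | None = None

    def __post_init__(self):
        if (self.counts < 0).any():
            raise ValueError("negative alignment count")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if not self.counts.index.equals(self.lengths.index):
            raise ValueError("counts and lengths indexed by different contigs")

    def coverage(self) -> pd.Series:
        """Mean fold-coverage per contig: alignments * read_length / length."""
        return self.counts * self.read_length / self.lengths

    # -- io -----------------------------------------------------------
    def write_tsv(self, path) -> None:
        path = Path(path)
        df = pd.DataFrame({
            "contig": self.counts.index,
            "length": self.lengths.values,
            "alignments": self.counts.values,
            "coverage": self.coverage().values,
        })
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        meta = {
            "sample_id": self.sample_id,
            "regime": self.regime,
            "library_total_reads": int(self.library_total_reads),
            "read_length": int(self.read_length),
            "min_identity": self.min_identity,
        }
        Path(str(path) + ".meta.json").write_text(
            json.dumps(meta, sort_keys=True, indent=1) + "\n")

    @classmethod
    def read_tsv(cls, path) -> "AlignmentCounts":
        df = pd.read_csv(path, sep="\t")
        meta = json.loads(Path(str(path) + ".meta.json").read_text())
        return cls(
            sample_id=meta["sample_id"],
            regime=meta["regime"],
            counts=pd.Series(df["alignments"].values, index=df["contig"], name="alignments"),
            lengths=pd.Series(df["length"].values, index=df["contig"], name="length"),
            library_total_reads=meta["library_total_reads"],
            read_length=meta["read_length"],
            min_identity=meta.get("min_identity"),
        )


def coverage_per_contig(counts: AlignmentCounts) -> pd.Series:
    """Per-contig mean coverage implied by alignment counts."""
    return counts.coverage()


# ---------------------------------------------------------------------------
# EXACT regime
# ---------------------------------------------------------------------------

_VERIFY_CHUNK = 500_000


def _strand_variants(reads: ReadSet, both_strands: bool):
    """Yield (strand_id, code matrix) with read N remapped to a never-match code."""
    fwd = reads.codes.copy()
    fwd[fwd == N] = _READ_N
    yield 0, fwd
    if both_strands:
        rev = reads.codes[:, ::-1].copy()
        m = rev < 4
        rev[m] = 3 - rev[m]
        rev[rev == N] = _READ_N
        yield 1, rev


def count_exact(reads: ReadSet, contigs: ContigSet,
                both_strands: bool = True) -> AlignmentCounts:
    """Count zero-mismatch whole-read placements per contig.

    Every (read, offset, strand) triple where the full read equals the contig
    substring contributes one alignment; reads and offsets are multi-counted
    as the chromosome-quotient statistic requires.
    """
    if reads.n_reads == 0 or len(contigs) == 0:
        raise ValueError("empty read set or contig set")
    L = reads.read_length
    g = _Genome(contigs)
    w = _window_hashes(g.cat, L)
    order = np.argsort(w, kind="stable")
    ws = w[order]
    pw = _powers(L, _BASE)
    tallies = np.zeros(len(contigs), dtype=np.int64)
    for _strand, rcodes in _strand_variants(reads, both_strands):
        h = _row_hashes(rcodes, pw)
        lo = np.searchsorted(ws, h, side="left")
        hi = np.searchsorted(ws, h, side="right")
        ridx, sidx = _expand_ranges(lo, hi)
        pos = order[sidx]
        span = np.arange(L, dtype=np.int64)
        for a in range(0, pos.size, _VERIFY_CHUNK):
            b = min(a + _VERIFY_CHUNK, pos.size)
            win = g.cat[pos[a:b, None] + span]
            ok = (win == rcodes[ridx[a:b]]).all(axis=1)
            if ok.any():
                cid = g.contig_of(pos[a:b][ok])
                tallies += np.bincount(cid, minlength=len(contigs))
    return AlignmentCounts(
        sample_id=reads.sample_id,
        regime=EXACT,
        counts=pd.Series(tallies, index=pd.Index(contigs.names, name="contig"),
                         name="alignments"),
        lengths=pd.Series(contigs.lengths, index=pd.Index(contigs.names, name="contig"),
                          name="length"),
        library_total_reads=reads.n_reads,
        read_length=L,
    )


# ---------------------------------------------------------------------------
# IDENT80 regime (best ungapped full-length placement per read)
# ---------------------------------------------------------------------------

_QGRAM_CAND_CAP = 3e7  # auto mode: switch to heuristic seeding above this volume


def count_ident(reads: ReadSet, contigs: ContigSet, min_identity: float = 0.8,
                both_strands: bool = True, method: str = "auto",
                seed_k: int = 15) -> AlignmentCounts:
    """Count best ungapped full-length placements at >= min_identity.

    A placement is admissible when its mismatch count is at most
    ``floor((1 - min_identity) * read_length)``; each read contributes one
    alignment at its best admissible placement (fewest mismatches, ties to
    the lexicographically lowest contig name, lowest offset, forward strand).

    ``method``:
      * ``"qgram"``  — seeds of length ``floor(L / (budget + 1))``; by the
        pigeonhole principle every admissible placement contains an exact
        seed, so the result equals an exhaustive scan.
      * ``"seed"``   — non-overlapping seeds of length ``seed_k``; complete
        for placements with fewer than ``L // seed_k`` mismatches, heuristic
        beyond that.
      * ``"auto"``   — qgram when the estimated candidate volume is small
        enough, else seed.
    """
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must be in (0, 1]")
    if reads.n_reads == 0 or len(contigs) == 0:
        raise ValueError("empty read set or contig set")
    L = reads.read_length
    budget = int(np.floor((1.0 - min_identity) * L + 1e-9))
    g = _Genome(contigs)

    k_exhaustive = max(1, L // (budget + 1))
    if method == "auto":
        n_strands = 2 if both_strands else 1
        s = L // k_exhaustive
        est = reads.n_reads * s * n_strands * (g.cat.size / 4 ** min(k_exhaustive, 16) + 1)
        method = "qgram" if est <= _QGRAM_CAND_CAP else "seed"
    if method == "qgram":
        k = k_exhaustive
    elif method == "seed":
        k = min(seed_k, L)
    else:
        raise ValueError(f"unknown method {method!r}")
    log.debug("count_ident: method=%s k=%d budget=%d", method, k, budget)

    kw = _window_hashes(g.cat, k)
    korder = np.argsort(kw, kind="stable")
    kws = kw[korder]
    pwk = _powers(k, _BASE)
    offsets = range(0, (L // k) * k, k)

    best_mm = np.full(reads.n_reads, budget + 1, dtype=np.int64)
    best_key = np.full((reads.n_reads, 3), np.iinfo(np.int64).max, dtype=np.int64)
    best_cid = np.full(reads.n_reads, -1, dtype=np.int64)

    span = np.arange(L, dtype=np.int64)
    max_diag = g.cat.size - L
    for strand, rcodes in _strand_variants(reads, both_strands):
        cand_r: list[np.ndarray] = []
        cand_d: list[np.ndarray] = []
        for off in offsets:
            h = _row_hashes(rcodes[:, off : off + k], pwk)
            lo = np.searchsorted(kws, h, side="left")
            hi = np.searchsorted(kws, h, side="right")
            ridx, sidx = _expand_ranges(lo, hi)
            diag = korder[sidx] - off
            keep = (diag >= 0) & (diag <= max_diag)
            cand_r.append(ridx[keep])
            cand_d.append(diag[keep])
        if not cand_r:
            continue
        ridx = np.concatenate(cand_r)
        diag = np.concatenate(cand_d)
        if ridx.size == 0:
            continue
        # dedupe (read, diagonal) pairs
        key = ridx * np.int64(max_diag + 1) + diag
        key = np.unique(key)
        ridx = key // np.int64(max_diag + 1)
        diag = key % np.int64(max_diag + 1)
        # placements must sit inside a single contig
        cid = g.contig_of(diag)
        inside = (diag + L) <= g.ends[cid]
        ridx, diag, cid = ridx[inside], diag[inside], cid[inside]
        for a in range(0, ridx.size, _VERIFY_CHUNK):
            b = min(a + _VERIFY_CHUNK, ridx.size)
            win = g.cat[diag[a:b, None] + span]
            mm = (win != rcodes[ridx[a:b]]).sum(axis=1).astype(np.int64)
            ok = mm <= budget
            if not ok.any():
                continue
            r = ridx[a:b][ok]
            m = mm[ok]
            c = cid[a:b][ok]
            o = diag[a:b][ok] - g.starts[c]
            nr = g.name_rank[c]
            st = np.full(r.size, strand, dtype=np.int64)
            # keep the best placement per read (lexicographic key)
            better = (
                (m < best_mm[r])
                | ((m == best_mm[r]) & (nr < best_key[r, 0]))
                | ((m == best_mm[r]) & (nr == best_key[r, 0]) & (o < best_key[r, 1]))
                | ((m == best_mm[r]) & (nr == best_key[r, 0]) & (o == best_key[r, 1])
                   & (st < best_key[r, 2]))
            )
            # within this chunk the same read can appear several times; iterate
            # in sorted-key order so the final assignment is the minimum
            if better.any():
                rb, mb, cb = r[better], m[better], c[better]
                ob, nb, sb = o[better], nr[better], st[better]
                order2 = np.lexsort((sb, ob, nb, mb, rb))[::-1]
                # reversed: later assignments win, so apply worst-to-best
                best_mm[rb[order2]] = mb[order2]
                best_key[rb[order2], 0] = nb[order2]
                best_key[rb[order2], 1] = ob[order2]
                best_key[rb[order2], 2] = sb[order2]
                best_cid[rb[order2]] = cb[order2]

    placed = best_cid >= 0
    tallies = np.bincount(best_cid[placed], minlength=len(contigs))
    return AlignmentCounts(
        sample_id=reads.sample_id,
        regime=IDENT80,
        counts=pd.Series(tallies, index=pd.Index(contigs.names, name="contig"),
                         name="alignments"),
        lengths=pd.Series(contigs.lengths, index=pd.Index(contigs.names, name="contig"),
                          name="length"),
        library_total_reads=reads.n_reads,
        read_length=L,
        min_identity=min_identity,
    )
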