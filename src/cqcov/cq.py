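"""Chromosome quotients: classifying contigs as putative X, Y or autosomal.

The chromosome quotient (CQ) of a contig is the ratio of female to male
alignment counts under zero-mismatch whole-read matching.  With equal
effective library depths the expectations are CQ = 2 for X-linked contigs
(two female copies against one male copy), CQ = 0 for Y-linked contigs and
CQ = 1 for autosomes.  Classification uses the bands

* putative Y: CQ < 0.3 (strict; the slack above 0 absorbs repetitive Y
  sequence shared with the female genome),
* putative X: 1.6 <= CQ <= 2.5 (both endpoints inclusive).

Library-size normalisation (on by default) divides each count by its
library total so that unequal sequencing depths do not shift the bands;
the unnormalised mode reproduces the literal alignment-count ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matching import EXACT, AlignmentCounts, ContigSet

log = logging.getLogger(__name__)

PUTATIVE_X = "PUTATIVE_X"
PUTATIVE_Y = "PUTATIVE_Y"
UNCLASSIFIED = "UNCLASSIFIED"
LOW_EVIDENCE = "LOW_EVIDENCE"
CALLS = (PUTATIVE_X, PUTATIVE_Y, UNCLASSIFIED, LOW_EVIDENCE)


@dataclass
class CQConfig:
    """Thresholds for chromosome-quotient classification."""

    y_max: float = 0.3          # putative Y: CQ strictly below this
    x_min: float = 1.6          # putative X band, inclusive
    x_max: float = 2.5
    min_support: int = 10       # combined F+M alignments below this -> LOW_EVIDENCE
    normalize: bool = True      # divide counts by library totals

    def __post_init__(self):
        if not 0 <= self.y_max < self.x_min < self.x_max:
            raise ValueError("need 0 <= y_max < x_min < x_max")
        if self.min_support < 0:
            raise ValueError("min_support must be >= 0")


@dataclass
class CQTable:
    """Per-contig chromosome quotients and calls for one female/male pairing."""

    table: pd.DataFrame          # contig, length, f_count, m_count, cq, call
    female_sample_id: str
    male_sample_id: str
    config: CQConfig

    def putative(self, call: str) -> list[str]:
        return self.table.loc[self.table["call"] == call, "contig"].tolist()

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def compute_cq(female: AlignmentCounts, male: AlignmentCounts,
               config: CQConfig | None = None) -> CQTable:
    """Compute per-contig chromosome quotients and classify them.

    Both count tables must come from the EXACT regime over the same contig
    set.  ``cq = (F_c / F_total) / (M_c / M_total)`` when normalising, else
    ``F_c / M_c``.  A contig with male count 0 but female evidence gets an
    infinite sentinel and stays unclassified; a contig without any
    alignments (or fewer than ``min_support`` combined) is LOW_EVIDENCE.
    """
    config = config or CQConfig()
    for counts in (female, male):
        if counts.regime != EXACT:
            raise ValueError(f"{counts.sample_id}: CQ requires EXACT-regime counts")
    if not female.counts.index.equals(male.counts.index):
        raise ValueError("female and male counts cover different contig sets")
    f = female.counts.to_numpy(dtype=float)
    m = male.counts.to_numpy(dtype=float)
    if config.normalize:
        if female.library_total_reads <= 0 or male.library_total_reads <= 0:
            raise ValueError("library totals must be positive to normalise")
        scale = male.library_total_reads / female.library_total_reads
    else:
        scale = 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cq = np.where(m > 0, f / m * scale,
                      np.where(f > 0, np.inf, np.nan))
    table = pd.DataFrame({
        "contig": female.counts.index,
        "length": female.lengths.to_numpy(),
        "f_count": female.counts.to_numpy(),
        "m_count": male.counts.to_numpy(),
        "cq": cq,
    })
    out = CQTable(table, female.sample_id, male.sample_id, config)
    return classify_cq(out, config)


def classify_cq(cqtable: CQTable, config: CQConfig | None = None) -> CQTable:
    """(Re-)apply the classification bands to a computed CQ table."""
    config = config or cqtable.config
    t = cqtable.table
    cq = t["cq"].to_numpy()
    support = t["f_count"].to_numpy() + t["m_count"].to_numpy()
    call = np.full(len(t), UNCLASSIFIED, dtype=object)
    with np.errstate(invalid="ignore"):
        call[cq < config.y_max] = PUTATIVE_Y
        call[(cq >= config.x_min) & (cq <= config.x_max)] = PUTATIVE_X
    call[(support < config.min_support) | (support == 0)] = LOW_EVIDENCE
    t = t.copy()
    t["call"] = call
    return CQTable(t, cqtable.female_sample_id, cqtable.male_sample_id, config)


def summarize_cq(cqtable: CQTable) -> pd.DataFrame:
    """Contig counts and total bases per call class."""
    t = cqtable.table
    rows = []
    for call in CALLS:
        sub = t[t["call"] == call]
        rows.append((call, len(sub), int(sub["length"].sum())))
    return pd.DataFrame(rows, columns=["call", "n_contigs", "total_bases"])


# ---------------------------------------------------------------------------
# dual-female representative X set
# ---------------------------------------------------------------------------


def _best_identity(short: np.ndarray, long: np.ndarray) -> float:
    """Best ungapped placement identity of `short` along `long`, both strands."""
    ls = short.size
    windows = np.lib.stride_tricks.sliding_window_view(long, ls)
    best = 0
    for probe in (short, _rc(short)):
        matches = (windows == probe).sum(axis=1).max()
        best = max(best, int(matches))
    return best / ls


def _rc(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    m = out < 4
    out[m] = 3 - out[m]
    return out


def consensus_x(x_a: ContigSet, x_b: ContigSet, min_identity: float = 0.8,
                min_len_ratio: float = 0.8) -> tuple[ContigSet | None, pd.DataFrame]:
    """Greedy cross-set clustering of two putative-X sets at 80/80 cutoffs.

    Each contig of the smaller set is matched to at most one unused contig of
    the larger set when (a) the shorter sequence of the pair reaches
    ``min_identity`` over its full length at its best ungapped placement on
    the longer (either strand) and (b) the length ratio (shorter/longer) is
    at least ``min_len_ratio``.  The representative of a matched pair is its
    longer member.  Sets are processed in descending length (ties by name),
    so the result is deterministic.

    Returns the representative contig set (None when nothing matched) and a
    report of pairs and unmatched contigs.
    """
    if len(x_a) == 0 or len(x_b) == 0:
        log.warning("consensus_x: empty input set")
        return None, pd.DataFrame(columns=["small", "large", "identity",
                                           "len_ratio", "representative"])
    small, large = (x_a, x_b) if len(x_a) <= len(x_b) else (x_b, x_a)

    def ordering(cs: ContigSet) -> list[int]:
        return sorted(range(len(cs)), key=lambda i: (-cs.lengths[i], cs.names[i]))

    used: set[int] = set()
    pairs = []
    for i in ordering(small):
        si = small.seqs[i]
        for j in ordering(large):
            if j in used:
                continue
            lj = large.seqs[j]
            shorter, longer = (si, lj) if si.size <= lj.size else (lj, si)
            ratio = shorter.size / longer.size
            if ratio < min_len_ratio:
                continue
            ident = _best_identity(shorter, longer)
            if ident >= min_identity:
                used.add(j)
                pairs.append((small.names[i], large.names[j], ident, ratio))
                break
    rep_names, rep_seqs = [], []
    rows = []
    for sname, lname, ident, ratio in pairs:
        si = small.seqs[small.names.index(sname)]
        lj = large.seqs[large.names.index(lname)]
        if si.size >= lj.size:
            rep, seq = sname, si
        else:
            rep, seq = lname, lj
        rows.append((sname, lname, ident, ratio, rep))
        if rep not in rep_names:  # the same contig may represent itself in both sets
            rep_names.append(rep)
            rep_seqs.append(seq)
    report = pd.DataFrame(rows, columns=["small", "large", "identity",
                                         "len_ratio", "representative"])
    matched_small = {r[0] for r in rows}
    matched_large = {r[1] for r in rows}
    report.attrs["unmatched_small"] = [n for n in small.names if n not in matched_small]
    report.attrs["unmatched_large"] = [n for n in large.names if n not in matched_large]
    reps = ContigSet(rep_names, rep_seqs) if rep_names else None
    return reps, report


def overlap_proportion(names_a, names_b) -> float:
    """Shared fraction of two contig-name sets, relative to the smaller set."""
    a, b = set(names_a), set(names_b)
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))
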