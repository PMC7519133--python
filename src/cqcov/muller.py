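"""Muller-element X-linkage from normalized male/female coverage.

Contigs anchored to the six conserved dipteran chromosome arms (Muller
elements A-F) are tested for X-linkage by comparing male against female
read coverage under full-length >= 80 %-identity matching.  Counts are first
equalised with median-of-ratios size factors (the standard normalisation of
count-based differential-coverage analysis), then each contig's
``log2(M/F)`` normalized coverage ratio is computed with a pseudocount.
A contig is called X-linked when the ratio falls in the band [-1.3, -0.6]
(inclusive): one male copy against two female copies gives an expectation
of -1.  An element is flagged sex-linked when at least ``flag_threshold``
of its anchored contigs are X-linked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matching import AlignmentCounts

log = logging.getLogger(__name__)

XLINK_BAND = (-1.3, -0.6)


# ---------------------------------------------------------------------------
# size factors (median-of-ratios)
# ---------------------------------------------------------------------------


def size_factors(count_matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors for a contigs x samples count matrix.

    For each contig with a positive geometric mean across samples, the ratio
    of each sample's count to that geometric mean is formed; a sample's
    factor is the median of its ratios, rescaled so the factors have
    geometric mean 1.  Dividing counts by the factors equalises depth
    against the pseudo-reference sample.
    """
    if count_matrix.shape[1] < 2:
        raise ValueError("size factors need at least two samples")
    counts = count_matrix.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no contig has nonzero counts in every sample; "
                         "cannot form the pseudo-reference")
    logc = np.log(counts[all_pos])
    loggeo = logc.mean(axis=1, keepdims=True)
    logfac = np.median(logc - loggeo, axis=0)
    logfac = logfac - logfac.mean()  # geometric mean of the factors = 1
    return pd.Series(np.exp(logfac), index=count_matrix.columns, name="size_factor")


def pool_counts(parts: list[AlignmentCounts], sample_id: str | None = None) -> AlignmentCounts:
    """Sum alignment counts of several libraries of the same sex into one.

    Used to pool the two female types before the Muller comparison; the
    libraries must share contig set, regime and read length.
    """
    if not parts:
        raise ValueError("nothing to pool")
    first = parts[0]
    for p in parts[1:]:
        if p.regime != first.regime or p.read_length != first.read_length:
            raise ValueError("pooled libraries must share regime and read length")
        if not p.counts.index.equals(first.counts.index):
            raise ValueError("pooled libraries cover different contig sets")
    return AlignmentCounts(
        sample_id=sample_id or "+".join(p.sample_id for p in parts),
        regime=first.regime,
        counts=sum((p.counts for p in parts[1:]), first.counts.copy()),
        lengths=first.lengths,
        library_total_reads=sum(p.library_total_reads for p in parts),
        read_length=first.read_length,
        min_identity=first.min_identity,
    )


# ---------------------------------------------------------------------------
# log2(M/F) linkage table
# ---------------------------------------------------------------------------


@dataclass
class LinkageTable:
    """Per-contig normalized-coverage comparison with X-linkage calls."""

    table: pd.DataFrame   # contig, element, length, m/f counts & norm cov, log2_mf, xlinked
    male_sample_id: str
    female_sample_id: str
    band: tuple[float, float]
    pseudocount: float

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def log2_mf(male: AlignmentCounts, female: AlignmentCounts,
            anchors: pd.DataFrame, factors: pd.Series | None = None,
            pseudocount: float = 0.5,
            band: tuple[float, float] = XLINK_BAND) -> LinkageTable:
    """Per-contig log2(M/F) normalized coverage ratio over anchored contigs.

    ``log2_mf(c) = log2((M_c/f_M + eps) / (F_c/f_F + eps))`` with
    pseudocount ``eps`` guarding against zero counts; a contig is X-linked
    when the ratio lies inside ``band`` (inclusive at both ends).  Anchors
    naming contigs absent from the counts are dropped with a warning.
    """
    if band[0] > band[1]:
        raise ValueError("band must be (low, high)")
    if not male.counts.index.equals(female.counts.index):
        raise ValueError("male and female counts cover different contig sets")
    if factors is None:
        factors = size_factors(pd.DataFrame({
            male.sample_id: male.counts,
            female.sample_id: female.counts,
        }))
    try:
        f_m = float(factors[male.sample_id])
        f_f = float(factors[female.sample_id])
    except KeyError as exc:
        raise ValueError(f"size factors missing sample {exc}") from None
    missing = ~anchors["contig"].isin(male.counts.index)
    if missing.any():
        log.warning("dropping %d anchored contigs absent from the counts",
                    int(missing.sum()))
    anchors = anchors[~missing]
    idx = anchors["contig"].to_numpy()
    m_norm = male.counts.loc[idx].to_numpy(dtype=float) / f_m
    f_norm = female.counts.loc[idx].to_numpy(dtype=float) / f_f
    lengths = male.lengths.loc[idx].to_numpy()
    ratio = np.log2((m_norm + pseudocount) / (f_norm + pseudocount))
    xlinked = (ratio >= band[0]) & (ratio <= band[1])
    table = pd.DataFrame({
        "contig": idx,
        "element": anchors["element"].to_numpy(),
        "length": lengths,
        "male_count": male.counts.loc[idx].to_numpy(),
        "female_count": female.counts.loc[idx].to_numpy(),
        "male_norm_cov": m_norm * male.read_length / lengths,
        "female_norm_cov": f_norm * female.read_length / lengths,
        "log2_mf": ratio,
        "xlinked": xlinked,
    })
    return LinkageTable(table, male.sample_id, female.sample_id, band, pseudocount)


def element_report(linkage: LinkageTable,
                   flag_threshold: float = 0.5) -> pd.DataFrame:
    """Per-element tally: anchored contigs, X-linked contigs and the fraction.

    An element is flagged SEX_LINKED when its X-linked fraction reaches
    ``flag_threshold``.
    """
    if not 0 < flag_threshold <= 1:
        raise ValueError("flag_threshold must be in (0, 1]")
    rows = []
    for element, sub in linkage.table.groupby("element", sort=True):
        n = len(sub)
        nx = int(sub["xlinked"].sum())
        frac = nx / n
        rows.append((element, n, nx, frac, frac >= flag_threshold))
    return pd.DataFrame(rows, columns=["element", "n_contigs", "n_xlinked",
                                       "fraction_xlinked", "sex_linked"])
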