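"""Synthetic genomes, sex-typed read libraries and truth tables.

The generator emulates the data a sex-chromosome coverage analysis consumes:
a diploid genome assembled once per contig, sequenced as short single-end
reads in a male and one or two female libraries.  Four segment classes carry
the copy-number structure of interest:

* ``AUTOSOME``       — 2 copies per diploid genome in both sexes;
* ``X_LINKED``       — 2 copies in females, 1 in males;
* ``Y_LINKED``       — 0 copies in females, 1 in males, with an optional
  ``y_leak`` fraction of the segment also present in females at autosomal
  copy number (repetitive Y material shared between the sexes — the reason
  the putative-Y chromosome-quotient threshold is 0.3 rather than 0);
* ``DUP_COLLAPSED``  — a duplicated region assembled into a single contig
  (4 copies per diploid genome in both sexes), producing the doubled-depth
  right mode of a bimodal coverage histogram.

Expected read throughput from a contig of length ``l`` with ``c`` copies is
``mean_depth * l * c / 2`` bases, i.e. ``mean_depth`` is the fold-coverage
of the ordinary two-copy diploid state.  Read counts are Poisson, start
positions and strands uniform, errors i.i.d. substitutions.  Every read
name records its contig of origin so oracle tests can audit placements.
All outputs are deterministic given the seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matching import ContigSet, ReadSet, revcomp

log = logging.getLogger(__name__)

AUTOSOME = "AUTOSOME"
X_LINKED = "X_LINKED"
Y_LINKED = "Y_LINKED"
DUP_COLLAPSED = "DUP_COLLAPSED"
KLASSES = (AUTOSOME, X_LINKED, Y_LINKED, DUP_COLLAPSED)

#: (female_copies, male_copies) per diploid genome
DEFAULT_COPIES = {
    AUTOSOME: (2, 2),
    X_LINKED: (2, 1),
    Y_LINKED: (0, 1),
    DUP_COLLAPSED: (4, 4),
}

MULLER_ELEMENTS = ("A", "B", "C", "D", "E", "F")

SEX_TYPES = ("M", "TF", "AF")  # male, thelygenic female, arrhenogenic female


@dataclass
class SegmentSpec:
    """One genomic segment: a contig of the assembly with per-sex copy numbers."""

    name: str
    length: int
    klass: str
    female_copies: int | None = None
    male_copies: int | None = None
    y_leak: float = 0.0
    muller_element: str | None = None

    def __post_init__(self):
        if self.klass not in KLASSES:
            raise ValueError(f"unknown segment class {self.klass!r}")
        if self.length <= 0:
            raise ValueError(f"segment {self.name!r}: length must be > 0")
        fdefault, mdefault = DEFAULT_COPIES[self.klass]
        if self.female_copies is None:
            self.female_copies = fdefault
        if self.male_copies is None:
            self.male_copies = mdefault
        if self.female_copies < 0 or self.male_copies < 0:
            raise ValueError(f"segment {self.name!r}: copies must be >= 0")
        if not 0 <= self.y_leak < 1:
            raise ValueError(f"segment {self.name!r}: y_leak must be in [0, 1)")
        if self.y_leak > 0 and self.klass != Y_LINKED:
            raise ValueError(f"segment {self.name!r}: y_leak only applies to Y_LINKED")
        if self.muller_element is not None and self.muller_element not in MULLER_ELEMENTS:
            raise ValueError(f"segment {self.name!r}: muller_element must be A-F")


@dataclass
class GenomeBlueprint:
    """Declarative description of a synthetic assembly; the ground truth."""

    segments: list[SegmentSpec]
    base_composition: float = 0.35  # GC fraction; dipteran genomes are AT-rich
    seed: int = 0

    def __post_init__(self):
        if not self.segments:
            raise ValueError("blueprint needs at least one segment")
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ValueError("duplicate segment names in blueprint")
        if not 0.0 <= self.base_composition <= 1.0:
            raise ValueError("base_composition (GC fraction) must be in [0, 1]")


@dataclass
class SampleSpec:
    """One sequencing library: a sex type with depth, read length and error rate."""

    sample_id: str
    sex_type: str
    mean_depth: float
    read_length: int = 100
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sex_type not in SEX_TYPES:
            raise ValueError(f"sex_type must be one of {SEX_TYPES}")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")

    @property
    def is_female(self) -> bool:
        return self.sex_type in ("TF", "AF")


TRUTH_COLUMNS = ["name", "length", "klass", "female_copies", "male_copies",
                 "y_leak", "muller_element"]


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------


def build_genome(blueprint: GenomeBlueprint) -> tuple[ContigSet, pd.DataFrame]:
    """Draw one contig per segment (i.i.d. bases at the blueprint GC fraction).

    Returns the contig set and a truth table with one row per contig.
    """
    rng = np.random.default_rng(blueprint.seed)
    gc = blueprint.base_composition
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    names, seqs, rows = [], [], []
    for seg in blueprint.segments:
        codes = rng.choice(4, size=seg.length, p=probs).astype(np.uint8)
        names.append(seg.name)
        seqs.append(codes)
        rows.append((seg.name, seg.length, seg.klass, seg.female_copies,
                     seg.male_copies, seg.y_leak, seg.muller_element))
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return ContigSet(names, seqs), truth


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def _copies_for(row, sex_type: str) -> int:
    return int(row.male_copies if sex_type == "M" else row.female_copies)


def simulate_reads(genome: ContigSet, truth: pd.DataFrame,
                   spec: SampleSpec) -> ReadSet:
    """Simulate a single-end read library for one sample.

    Expected read bases from contig ``c`` equal
    ``mean_depth * length(c) * copies(c, sex) / 2``; female samples draw from
    Y segments only through the ``y_leak`` prefix (at two copies).  Read
    names carry provenance as ``<sample>.<i>:<contig>:<start>:<strand>``.
    """
    rng = np.random.default_rng(spec.seed)
    rl = spec.read_length
    chunks: list[np.ndarray] = []
    names: list[str] = []
    serial = 0
    for row in truth.itertuples(index=False):
        seq = genome.seqs[genome.names.index(row.name)]
        copies = _copies_for(row, spec.sex_type)
        pools: list[tuple[np.ndarray, float]] = []
        if copies > 0:
            pools.append((seq, copies))
        if spec.is_female and row.klass == Y_LINKED and row.y_leak > 0:
            leak_len = int(round(row.y_leak * row.length))
            if leak_len > 0:
                pools.append((seq[:leak_len], 2))
        for pool, cp in pools:
            if rl > pool.size:
                log.warning("contig %s: pool shorter than read length, no reads",
                            row.name)
                continue
            expected = spec.mean_depth * pool.size * (cp / 2) / rl
            n = int(rng.poisson(expected))
            if n == 0:
                continue
            starts = rng.integers(0, pool.size - rl + 1, size=n)
            strands = rng.integers(0, 2, size=n)
            windows = np.lib.stride_tricks.sliding_window_view(pool, rl)
            mat = windows[starts].copy()
            flip = strands == 1
            if flip.any():
                sub = mat[flip][:, ::-1]
                m = sub < 4
                sub[m] = 3 - sub[m]
                mat[flip] = sub
            if spec.error_rate > 0:
                err = rng.random(mat.shape) < spec.error_rate
                if err.any():
                    shift = rng.integers(1, 4, size=int(err.sum())).astype(np.uint8)
                    base = mat[err]
                    ok = base < 4
                    base[ok] = (base[ok] + shift[ok]) % 4
                    mat[err] = base
            chunks.append(mat)
            for st, sd in zip(starts, strands):
                names.append(f"{spec.sample_id}.{serial}:{row.name}:{st}:{'+-'[sd]}")
                serial += 1
    if not chunks:
        log.warning("sample %s: no reads simulated", spec.sample_id)
        return ReadSet(np.empty((0, rl), dtype=np.uint8), [], spec.sample_id)
    return ReadSet(np.vstack(chunks), names, spec.sample_id)


def read_origin(read_name: str) -> tuple[str, int, str]:
    """Parse (contig, start, strand) provenance out of a simulated read name."""
    _serial, contig, start, strand = read_name.rsplit(":", 3)
    return contig, int(start), strand


def simulate_contig_coverages(truth: pd.DataFrame, spec: SampleSpec) -> pd.DataFrame:
    """Draw per-contig mean coverages directly from the read-count model.

    Marginalises the read simulation: the number of reads on a contig is
    Poisson with mean ``depth * length * copies / 2 / read_length`` and the
    realised coverage is ``reads * read_length / length``.  Useful for
    exercising the coverage-mixture stage at scales where simulating and
    matching individual reads adds nothing.
    """
    rng = np.random.default_rng(spec.seed)
    copies = np.where(truth["klass"].eq(Y_LINKED) & (spec.sex_type != "M"),
                      0,
                      [(r.male_copies if spec.sex_type == "M" else r.female_copies)
                       for r in truth.itertuples(index=False)])
    lam = spec.mean_depth * truth["length"].to_numpy() * (copies / 2) / spec.read_length
    n = rng.poisson(lam)
    cov = n * spec.read_length / truth["length"].to_numpy()
    return pd.DataFrame({"contig": truth["name"], "coverage": cov,
                         "length": truth["length"]})


# ---------------------------------------------------------------------------
# anchor tables (Muller-element assignment stand-in)
# ---------------------------------------------------------------------------


def make_anchor_table(truth: pd.DataFrame,
                      elements: dict[str, str] | None = None,
                      mislabel_rate: float = 0.0,
                      seed: int = 0) -> pd.DataFrame:
    """Build a (contig, element) anchor table, optionally with label noise.

    ``elements`` maps contigs to Muller elements A-F; by default the truth
    table's ``muller_element`` column is used.  A ``mislabel_rate`` fraction
    of rows is reassigned uniformly at random to a wrong element, emulating
    noisy homology-based assignment.
    """
    if not 0.0 <= mislabel_rate <= 1.0:
        raise ValueError("mislabel_rate must be in [0, 1]")
    if elements is None:
        anchored = truth[truth["muller_element"].notna()]
        elements = dict(zip(anchored["name"], anchored["muller_element"]))
    bad = set(elements.values()) - set(MULLER_ELEMENTS)
    if bad:
        raise ValueError(f"elements outside A-F: {sorted(bad)}")
    table = pd.DataFrame({"contig": list(elements), "element": list(elements.values())})
    if mislabel_rate > 0:
        universe = sorted(set(elements.values()))
        if len(universe) < 2:
            raise ValueError("mislabelling requires at least two distinct elements")
        rng = np.random.default_rng(seed)
        flip = rng.random(len(table)) < mislabel_rate
        for i in np.flatnonzero(flip):
            wrong = [e for e in universe if e != table.at[i, "element"]]
            table.at[i, "element"] = wrong[rng.integers(len(wrong))]
    return table


# ---------------------------------------------------------------------------
# tabular io
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_anchor_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"contig", "element"} <= set(df.columns):
        raise ValueError("anchor table needs 'contig' and 'element' columns")
    return df


def read_truth_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["muller_element"] = df["muller_element"].where(df["muller_element"].notna(), None)
    return df


def write_class_bed(truth: pd.DataFrame, path) -> None:
    """Export segment classes as BED (0-based, half-open, whole contigs)."""
    with open(path, "w") as fh:
        for row in truth.itertuples(index=False):
            fh.write(f"{row.name}\t0\t{row.length}\t{row.klass}\n")
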