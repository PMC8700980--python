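"""TF binding-motif handling: JASPAR parsing, log-odds PWMs, exact
p-value score thresholds, and strand-aware promoter scanning.

The score threshold for a requested match p-value is computed from the
exact distribution of PWM scores over i.i.d. background sequence, by
dynamic programming over discretized column scores.  Column log-odds
are rounded UP to the discretization grid before convolution, so the
realized false-positive probability at the returned threshold is
guaranteed to be at most the requested p-value (conservative,
one-sided).  The threshold is applied per position, with no correction
across positions: a fixed, strict per-match significance level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import motifs as bio_motifs

log = logging.getLogger("regcascade")

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

DEFAULT_BACKGROUND = (0.25, 0.25, 0.25, 0.25)
DEFAULT_PSEUDOCOUNT = 0.8
DEFAULT_GRANULARITY = 1e-3


class MotifError(ValueError):
    pass


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWMRecord:
    """A motif as a 4xL count matrix plus its derived log-odds form."""

    tf_name: str
    counts: np.ndarray                       # shape (4, L), rows A,C,G,T
    background: tuple = DEFAULT_BACKGROUND
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    log_odds: np.ndarray = field(init=False)
    threshold: float | None = None           # score units, set per p-value
    threshold_pvalue: float | None = None
    threshold_granularity: float = DEFAULT_GRANULARITY

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4 or self.counts.shape[1] < 1:
            raise MotifError(f"motif {self.tf_name}: counts must be 4 x L with L >= 1")
        if (self.counts < 0).any():
            raise MotifError(f"motif {self.tf_name}: negative count")
        colsum = self.counts.sum(axis=0)
        if (colsum <= 0).any():
            raise MotifError(f"motif {self.tf_name}: zero column sum")
        bg = np.asarray(self.background, dtype=float)
        pc = bg * self.pseudocount               # total pseudocount split by background
        self.log_odds = (np.log2((self.counts + pc[:, None])
                                 / (colsum[None, :] + self.pseudocount))
                         - np.log2(bg)[:, None])

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.counts, axis=0))

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    def reverse_complement(self) -> "PWMRecord":
        return PWMRecord(self.tf_name, self.counts[::-1, ::-1],
                         self.background, self.pseudocount)


@dataclass
class MotifHit:
    tf_name: str
    sequence_id: str
    offset: int          # 0-based start within the promoter sequence
    strand: str          # '+' or '-'
    score: float
    pvalue_bound: float  # the per-position p-value the threshold enforces


def parse_jaspar(path, background=DEFAULT_BACKGROUND,
                 pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[PWMRecord]:
    """Parse JASPAR PFM text (``>ID NAME`` then bracketed A/C/G/T rows).

    Row order in the file is irrelevant: rows are keyed by their base
    label and normalized to A,C,G,T.
    """
    with open(path) as fh:
        try:
            parsed = bio_motifs.parse(fh, "jaspar")
        except Exception as exc:
            raise MotifError(f"cannot parse JASPAR file {path}: {exc}") from exc
    records = []
    for m in parsed:
        name = m.name or m.matrix_id
        counts = np.array([list(m.counts[b]) for b in BASES], dtype=float)
        try:
            rec = PWMRecord(name, counts, tuple(background), pseudocount)
        except MotifError as exc:
            raise MotifError(f"{path}: {exc}") from exc
        records.append(rec)
    log.info("parse_jaspar: %d motifs from %s", len(records), path)
    return records


def write_jaspar(records: list[PWMRecord], path) -> None:
    with open(path, "w") as fh:
        for i, rec in enumerate(records, 1):
            fh.write(f">M{i:04d} {rec.tf_name}\n")
            for b, row in zip(BASES, rec.counts):
                cells = " ".join(f"{v:6.0f}" for v in row)
                fh.write(f"{b}  [{cells} ]\n")


def score_threshold_from_pvalue(pwm: PWMRecord, pvalue: float,
                                background=None,
                                granularity: float = DEFAULT_GRANULARITY) -> float:
    """Smallest discretized score s with P(score >= s) <= pvalue under the
    i.i.d. background, computed by exact DP over column score distributions.

    Column scores are rounded up to the granularity grid, so a true
    score can only fall below its binned value and the p-value guarantee
    is one-sided (never anti-conservative).  If even the single best
    word exceeds the budget, the maximum score is returned with a
    warning.  ``pvalue = 1`` returns the minimum achievable score.
    """
    if not (0.0 < pvalue <= 1.0):
        raise MotifError(f"pvalue must lie in (0, 1], got {pvalue}")
    bg = np.asarray(background if background is not None else pwm.background,
                    dtype=float)
    q = np.ceil(pwm.log_odds / granularity - 1e-9).astype(np.int64)
    dist: dict[int, float] = {0: 1.0}
    for j in range(pwm.length):
        new: dict[int, float] = {}
        for s, p in dist.items():
            for b in range(4):
                key = s + q[b, j]
                new[key] = new.get(key, 0.0) + p * bg[b]
        dist = new
    scores = sorted(dist, reverse=True)
    tail = 0.0
    threshold_bin = None
    for s in scores:
        tail += dist[s]
        if tail <= pvalue + 1e-15:
            threshold_bin = s
        else:
            break
    if threshold_bin is None:
        log.warning("score_threshold_from_pvalue: motif %s: p=%g below the "
                    "probability of the best word; using max score",
                    pwm.tf_name, pvalue)
        threshold_bin = scores[0]
    return float(threshold_bin * granularity)


def set_thresholds(pwms: list[PWMRecord], pvalue: float,
                   granularity: float = DEFAULT_GRANULARITY) -> None:
    for pwm in pwms:
        pwm.threshold = score_threshold_from_pvalue(pwm, pvalue,
                                                    granularity=granularity)
        pwm.threshold_pvalue = pvalue
        pwm.threshold_granularity = granularity


def promoter_interval(start: int, end: int, strand: str, upstream: int,
                      downstream: int) -> tuple[int, int]:
    """Genomic half-open window of the promoter of a gene at [start, end).

    The TSS is the strand-aware 5' end.  On the plus strand the window
    is [TSS - upstream, TSS + downstream); on the minus strand it is the
    strand-reflected interval (upstream = larger coordinates):
    [end - downstream, end + upstream).
    """
    if strand == "+":
        tss = start
        return tss - upstream, tss + downstream
    elif strand == "-":
        return end - downstream, end + upstream
    raise MotifError(f"unknown strand {strand!r}")


def extract_promoters(genes, genome: dict[str, str], upstream: int = 1000,
                      downstream: int = 200,
                      gene_classes: set[str] | None = None) -> dict[str, str]:
    """Promoter sequence per gene, 5'->3' on the gene's own strand.

    ``genes`` is a BED-like DataFrame (chrom, start, end, name, strand
    [, gene_class]).  Windows extending past a chromosome end are
    clipped with a warning.  If ``gene_classes`` is given, only genes of
    those classes are extracted.
    """
    promoters: dict[str, str] = {}
    for row in genes.itertuples(index=False):
        if gene_classes is not None and getattr(row, "gene_class", None) not in gene_classes:
            continue
        if row.chrom not in genome:
            raise MotifError(f"unknown chromosome {row.chrom!r} for gene {row.name}")
        chrom_seq = genome[row.chrom]
        a, b = promoter_interval(row.start, row.end, row.strand, upstream, downstream)
        ca, cb = max(a, 0), min(b, len(chrom_seq))
        if (ca, cb) != (a, b):
            log.warning("extract_promoters: window of %s clipped from [%d, %d) "
                        "to [%d, %d)", row.name, a, b, ca, cb)
        seq = chrom_seq[ca:cb].upper()
        if row.strand == "-":
            seq = revcomp(seq)
        promoters[row.name] = seq
    return promoters


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return codes


def _scan_one_strand(lo: np.ndarray, codes: np.ndarray) -> np.ndarray:
    L = lo.shape[1]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    # append a heavily penalized row for non-ACGT characters
    lo5 = np.vstack([lo, np.full((1, L), -1e9)])
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return lo5[windows, np.arange(L)].sum(axis=1)


def scan_promoters(pwms: list[PWMRecord], promoters: dict[str, str],
                   pvalue: float | None = None,
                   both_strands: bool = True) -> list[MotifHit]:
    """Slide every PWM over every promoter (both strands by default) and
    emit positions scoring at or above the motif's p-value threshold.

    Scoring happens on the same discretized (ceil-rounded) grid the
    threshold was computed on, so the realized per-position false-match
    probability equals the exact DP tail mass (<= the requested
    p-value).  Offsets are 0-based starts within the promoter sequence;
    a '-' strand hit means the reverse complement of the window matches
    the motif.  Promoters shorter than a motif are skipped with a log
    entry.
    """
    hits: list[MotifHit] = []
    for pwm in pwms:
        if pwm.threshold is None:
            if pvalue is None:
                raise MotifError(f"motif {pwm.tf_name}: no threshold set and "
                                 "no pvalue given")
            pwm.threshold = score_threshold_from_pvalue(pwm, pvalue)
            pwm.threshold_pvalue = pvalue
        g = pwm.threshold_granularity
        binned = np.ceil(pwm.log_odds / g - 1e-9) * g
        for seq_id in sorted(promoters):
            seq = promoters[seq_id].upper()
            if len(seq) < pwm.length:
                log.info("scan_promoters: %s shorter than motif %s, skipped",
                         seq_id, pwm.tf_name)
                continue
            codes = _encode(seq)
            strands = [("+", binned)]
            if both_strands:
                strands.append(("-", binned[::-1, ::-1]))
            for strand, lo in strands:
                scores = _scan_one_strand(lo, codes)
                for off in np.nonzero(scores >= pwm.threshold - 1e-9)[0]:
                    hits.append(MotifHit(pwm.tf_name, seq_id, int(off), strand,
                                         float(scores[off]),
                                         pwm.threshold_pvalue or float("nan")))
    hits.sort(key=lambda h: (h.tf_name, h.sequence_id, h.offset, h.strand))
    log.info("scan_promoters: %d motifs x %d promoters -> %d hits",
             len(pwms), len(promoters), len(hits))
    return hits


def hits_to_edges(hits: list[MotifHit]) -> list[tuple[str, str]]:
    """Distinct (TF, lncRNA) pairs with at least one significant match."""
    return sorted({(h.tf_name, h.sequence_id) for h in hits})
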