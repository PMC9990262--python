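"""PWM motif matching with DP-calibrated score thresholds, plus enrichment.

The scoring model
-----------------
A motif starts life as a position frequency matrix (PFM): raw base counts per
column.  :func:`build_pwm` converts it to a position weight matrix of
log2-odds in bits,

    pwm[b][j] = log2( (counts[b][j] + pc * bg[b]) / (col_total[j] + pc) / bg[b] )

with pseudocount ``pc`` distributed by the background frequencies ``bg``.
A window of sequence scores the sum of its per-position entries; the reverse
strand is scored with the reverse-complemented matrix so coordinates always
stay on the forward strand.

Threshold calibration
---------------------
The score cutoff for a target false positive rate is computed exactly: the
pmf of the score of a random background sequence of motif length is obtained
by discretizing each column's four scores to a fixed grid (rounding *down*,
so the reported tail is conservative) and convolving the per-column
distributions.  The threshold is the smallest grid score whose upper tail
mass is at or below the target FPR.

Enrichment
----------
Three Fisher-exact enrichment modes compare motif-hit frequencies between a
target and a background region set (user-provided background, randomly
relocated background, gene-association split, or promoter split), one-sided
in the enrichment direction, with Benjamini-Hochberg correction across the
motif set.
"""

from __future__ import annotations

import html as _html
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io import ChromTable, GeneSet
from .regions import Region, RegionSet, random_regions

__all__ = [
    "Motif",
    "MotifSet",
    "MotifMatch",
    "ScoreDistribution",
    "ThresholdResult",
    "EnrichmentRow",
    "build_pwm",
    "score_distribution",
    "threshold_for_fpr",
    "scan",
    "match_regions",
    "promoter_region",
    "associate_genes",
    "enrich_input_vs_background",
    "enrich_gene_assoc",
    "enrich_promoters",
    "bh_adjust",
    "report",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
UNIFORM_BG = np.array([0.25, 0.25, 0.25, 0.25])

DEFAULT_FPR = 1e-4          # calibration target for match thresholds
ADMISSIBLE_FPR = (1e-5, 1e-3)  # sensible user-facing range
DEFAULT_GRANULARITY = 0.01  # bits per grid step in the score pmf


@dataclass
class Motif:
    """A TF motif: PFM counts plus (once built) the log2-odds PWM."""

    id: str
    name: str
    counts: np.ndarray  # 4 x L, rows A,C,G,T
    pseudocount: float = 1.0
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())
    pwm: np.ndarray | None = None
    threshold: float | None = None
    threshold_reachable: bool = True

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.shape[0] != 4:
            raise ValueError("counts must have 4 rows (A,C,G,T)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.background <= 0).any() or abs(self.background.sum() - 1) > 1e-9:
            raise ValueError("background must be positive and sum to 1")

    def __len__(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))

    def max_score(self) -> float:
        if self.pwm is None:
            raise ValueError("build the PWM first")
        return float(self.pwm.max(axis=0).sum())


class MotifSet:
    """Motifs keyed by unique id, with a source-repository label."""

    def __init__(self, motifs: Iterable[Motif] = (), source: str = ""):
        self.motifs: dict[str, Motif] = {}
        self.source = source
        for m in motifs:
            self.add(m)

    def add(self, motif: Motif) -> None:
        if motif.id in self.motifs:
            raise ValueError(f"duplicate motif id {motif.id!r}")
        self.motifs[motif.id] = motif

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs.values())

    def __getitem__(self, motif_id: str) -> Motif:
        return self.motifs[motif_id]

    def __contains__(self, motif_id: str) -> bool:
        return motif_id in self.motifs


@dataclass(frozen=True)
class MotifMatch:
    """One above-threshold hit, coordinates on the forward strand."""

    start: int
    end: int
    motif_id: str
    score: float
    strand: str


def build_pwm(
    motif: Motif,
    pseudocount: float = 1.0,
    background: Sequence[float] | None = None,
) -> Motif:
    """Attach the log2-odds PWM (bits) to a motif, in place, and return it."""
    bg = UNIFORM_BG.copy() if background is None else np.asarray(background, float)
    col_totals = motif.counts.sum(axis=0)
    if (col_totals <= 0).any() and pseudocount == 0:
        raise ValueError("zero-count column with zero pseudocount")
    probs = (motif.counts + pseudocount * bg[:, None]) / (col_totals + pseudocount)
    motif.pwm = np.log2(probs / bg[:, None])
    motif.pseudocount = pseudocount
    motif.background = bg
    return motif


@dataclass
class ScoreDistribution:
    """Exact pmf of the background score on a discretized grid.

    ``probs[i]`` is the probability of grid score ``(offset + i)`` grid
    steps, i.e. bits = (offset + i) * granularity.
    """

    granularity: float
    offset: int
    probs: np.ndarray

    def __post_init__(self) -> None:
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("pmf must sum to 1")

    @property
    def grid_scores(self) -> np.ndarray:
        return (self.offset + np.arange(len(self.probs))) * self.granularity

    def tail(self, score_bits: float) -> float:
        """P(grid score >= score_bits)."""
        idx = int(np.ceil(score_bits / self.granularity - 1e-9)) - self.offset
        if idx <= 0:
            return 1.0
        if idx >= len(self.probs):
            return 0.0
        return float(self.probs[idx:].sum())


def discretize(pwm: np.ndarray, granularity: float = DEFAULT_GRANULARITY) -> np.ndarray:
    """Floor each PWM entry to the grid (integer steps); conservative tail.

    The 1e-9 nudge absorbs float jitter like 2.0/0.01 -> 199.999... so exact
    grid values are not pushed down a step.
    """
    return np.floor(pwm / granularity + 1e-9).astype(np.int64)


def score_distribution(
    motif: Motif, granularity: float = DEFAULT_GRANULARITY
) -> ScoreDistribution:
    """Exact background-score pmf via positionwise convolution.

    Each column contributes a 4-outcome distribution over its discretized
    scores weighted by the background base probabilities; the total-score pmf
    is their convolution.
    """
    if motif.pwm is None:
        build_pwm(motif, motif.pseudocount, motif.background)
    grid = discretize(motif.pwm, granularity)  # 4 x L ints
    bg = motif.background
    lo_total = int(grid.min(axis=0).sum())
    hi_total = int(grid.max(axis=0).sum())
    probs = np.array([1.0])
    offset = 0
    for j in range(grid.shape[1]):
        col = grid[:, j]
        lo, hi = int(col.min()), int(col.max())
        col_p = np.zeros(hi - lo + 1)
        for b in range(4):
            col_p[col[b] - lo] += bg[b]
        probs = np.convolve(probs, col_p)
        offset += lo
    assert offset == lo_total and offset + len(probs) - 1 == hi_total
    # guard against negative float dust from convolution
    probs = np.maximum(probs, 0.0)
    probs /= probs.sum()
    return ScoreDistribution(granularity, offset, probs)


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float       # bits, on the grid
    attained_fpr: float    # exact tail mass at the threshold
    reachable: bool        # False when no grid score satisfies the FPR


def threshold_for_fpr(
    motif: Motif,
    fpr: float = DEFAULT_FPR,
    granularity: float = DEFAULT_GRANULARITY,
) -> ThresholdResult:
    """Smallest grid score t with P(score >= t) <= fpr; sets motif.threshold.

    When even the maximum score has tail mass above ``fpr``, the returned
    threshold is one grid step past the maximum (no random sequence passes)
    and the result is flagged unreachable.
    """
    if not (0 < fpr < 1) and fpr != 1:
        raise ValueError("fpr must be in (0, 1]")
    dist = score_distribution(motif, granularity)
    tails = np.cumsum(dist.probs[::-1])[::-1]  # tails[i] = P(score >= grid i)
    ok = np.nonzero(tails <= fpr)[0]
    if len(ok):
        t_idx = int(ok[0])
        res = ThresholdResult(
            threshold=(dist.offset + t_idx) * granularity,
            attained_fpr=float(tails[t_idx]),
            reachable=True,
        )
    else:
        res = ThresholdResult(
            threshold=(dist.offset + len(dist.probs)) * granularity,
            attained_fpr=0.0,
            reachable=False,
        )
    motif.threshold = res.threshold
    motif.threshold_reachable = res.reachable
    return res


def _encode(sequence: str) -> np.ndarray:
    """ACGT -> 0..3; anything else (N) -> 4."""
    table = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, pwm: np.ndarray) -> np.ndarray:
    """Score every length-L window of the encoded sequence; N windows -> -inf."""
    L = pwm.shape[1]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    # pad the pwm with a -inf row for code 4 (N)
    padded = np.vstack([pwm, np.full((1, L), -np.inf)])
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    with np.errstate(invalid="ignore"):
        return padded[windows, np.arange(L)].sum(axis=1)


def reverse_complement_pwm(pwm: np.ndarray) -> np.ndarray:
    return pwm[::-1, ::-1]


def scan(
    sequence: str,
    motif: Motif,
    threshold: float | None = None,
    granularity: float = DEFAULT_GRANULARITY,
) -> list[MotifMatch]:
    """All above-threshold hits of the motif on both strands of a sequence.

    The match decision is made on the same discretized score grid the
    threshold was calibrated on, so the probability that a random background
    window matches equals the calibrated tail mass exactly.  Reported scores
    are the exact (undiscretized) bit scores, which are always >= the grid
    score and hence >= the threshold.

    Windows containing N are skipped.  Minus-strand windows are scored with
    the reverse-complement matrix; reported coordinates are always forward.
    """
    if motif.pwm is None:
        build_pwm(motif, motif.pseudocount, motif.background)
    if threshold is None:
        if motif.threshold is None:
            raise ValueError("no threshold: pass one or call threshold_for_fpr")
        threshold = motif.threshold
    t_grid = int(np.ceil(threshold / granularity - 1e-9))
    codes = _encode(sequence)
    L = len(motif)
    grid = discretize(motif.pwm, granularity).astype(float)
    matches = []
    for strand, mat, exact in (
        ("+", grid, motif.pwm),
        ("-", reverse_complement_pwm(grid), reverse_complement_pwm(motif.pwm)),
    ):
        scores = _window_scores(codes, mat)
        hits = np.nonzero(scores >= t_grid)[0]
        for i in hits:
            bits = float(sum(exact[codes[i + j], j] for j in range(L)))
            matches.append(MotifMatch(int(i), int(i) + L, motif.id, bits, strand))
    matches.sort(key=lambda m: (m.start, m.strand))
    return matches


def match_regions(
    regions: RegionSet,
    genome_fasta,
    motif_set: MotifSet,
    fpr: float = DEFAULT_FPR,
) -> RegionSet:
    """Motif-predicted binding sites (MPBS) for every motif in every region.

    Output regions carry name = motif id, score = bits x 100 rounded (BED
    score convention), strand of the hit; coordinates are genomic.
    """
    for m in motif_set:
        if m.threshold is None:
            threshold_for_fpr(m, fpr)
    out: list[Region] = []
    for region in regions:
        seq = str(genome_fasta[region.chrom][region.start : region.end])
        for m in motif_set:
            for hit in scan(seq, m):
                out.append(
                    Region(
                        region.chrom,
                        region.start + hit.start,
                        region.start + hit.end,
                        name=m.id,
                        score=round(hit.score * 100),
                        strand=hit.strand,
                    )
                )
    return RegionSet(out, name="mpbs").sort()


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentRow:
    """One motif's 2x2 Fisher table and (adjusted) p-value.

    a/b: target regions with/without a hit; c/d: background likewise.
    """

    motif_id: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    adjusted_p: float = 1.0

    def to_dict(self) -> dict:
        return {
            "motif": self.motif_id,
            "target_hits": self.a,
            "target_misses": self.b,
            "background_hits": self.c,
            "background_misses": self.d,
            "odds_ratio": self.odds_ratio,
            "p_value": self.p_value,
            "adjusted_p": self.adjusted_p,
        }


def fisher_enrichment_p(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher p (enrichment direction) = hypergeometric upper tail."""
    # P(X >= a), X ~ Hypergeom(N=a+b+c+d, K=a+c, n=a+b)
    return float(stats.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _regions_with_hit(
    regions: RegionSet, genome_fasta, motif: Motif
) -> int:
    """Number of regions containing >=1 hit of the motif (binary counting)."""
    count = 0
    for region in regions:
        seq = str(genome_fasta[region.chrom][region.start : region.end])
        if scan(seq, motif):
            count += 1
    return count


def _fisher_rows(
    target: RegionSet,
    background: RegionSet,
    genome_fasta,
    motif_set: MotifSet,
) -> list[EnrichmentRow]:
    rows = []
    for m in motif_set:
        a = _regions_with_hit(target, genome_fasta, m)
        c = _regions_with_hit(background, genome_fasta, m)
        b = len(target) - a
        d = len(background) - c
        odds = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else 0.0
        rows.append(
            EnrichmentRow(m.id, a, b, c, d, odds, fisher_enrichment_p(a, b, c, d))
        )
    adj = bh_adjust([r.p_value for r in rows])
    for r, q in zip(rows, adj):
        r.adjusted_p = float(q)
    rows.sort(key=lambda r: (r.adjusted_p, r.p_value, r.motif_id))
    return rows


def enrich_input_vs_background(
    target: RegionSet,
    background: RegionSet | None,
    genome_fasta,
    motif_set: MotifSet,
    fpr: float = DEFAULT_FPR,
    chrom_table: ChromTable | None = None,
    seed: int = 0,
    min_background: int = 1000,
) -> list[EnrichmentRow]:
    """Fisher enrichment of target regions against (possibly random) background.

    Without an explicit background, ``max(|target|, min_background)`` regions
    are drawn uniformly on the genome with lengths resampled from the target
    (seeded, reproducible).
    """
    if len(target) == 0:
        raise ValueError("target region set is empty")
    for m in motif_set:
        if m.threshold is None:
            threshold_for_fpr(m, fpr)
    if background is None:
        if chrom_table is None:
            raise ValueError("random background needs a chrom_table")
        background = random_regions(
            chrom_table,
            target.lengths(),
            max(len(target), min_background),
            seed,
        )
    return _fisher_rows(target, background, genome_fasta, motif_set)


def promoter_region(
    gene: Region, promoter_len: int, chrom_table: ChromTable | None = None
) -> Region:
    """Strand-aware promoter window: ``promoter_len`` bp upstream of the TSS."""
    if gene.strand == "+":
        s, e = gene.start - promoter_len, gene.start
    elif gene.strand == "-":
        s, e = gene.end, gene.end + promoter_len
    else:
        raise ValueError(f"gene {gene.name!r} has no strand")
    s = max(0, s)
    if chrom_table is not None and gene.chrom in chrom_table:
        e = min(e, chrom_table[gene.chrom])
    if s >= e:  # promoter falls entirely off the chromosome
        s, e = gene.start, gene.start + 1
    return Region(gene.chrom, s, e, gene.name, strand=gene.strand)


def associate_genes(
    regions: RegionSet,
    genes: GeneSet,
    promoter_len: int = 1000,
    distal_len: int = 50000,
) -> list[str | None]:
    """Per-region nearest-gene labels using promoter/body/distal windows.

    A region associates with a gene when it overlaps the gene body, the
    strand-aware promoter window, or lies within ``distal_len`` bp of the
    gene body.  The nearest gene (bp gap to the body, 0 when overlapping)
    wins; ties break toward the smallest gene id.
    """
    labels: list[str | None] = []
    for region in regions:
        best: tuple[int, str] | None = None
        for gene in genes:
            if gene.chrom != region.chrom:
                continue
            gap = max(gene.start - region.end, region.start - gene.end, 0)
            prom = promoter_region(gene, promoter_len)
            in_prom = prom.start < region.end and region.start < prom.end
            if gap == 0 or in_prom or gap <= distal_len:
                cand = (gap, gene.name)
                if best is None or cand < best:
                    best = cand
        labels.append(best[1] if best else None)
    return labels


def enrich_gene_assoc(
    regions: RegionSet,
    genes: GeneSet,
    genes_of_interest: Sequence[str],
    genome_fasta,
    motif_set: MotifSet,
    fpr: float = DEFAULT_FPR,
    promoter_len: int = 1000,
    distal_len: int = 50000,
) -> list[EnrichmentRow]:
    """Enrichment of regions associated with genes of interest vs the rest."""
    interest = set(genes_of_interest)
    if not interest:
        raise ValueError("empty gene-of-interest list")
    labels = associate_genes(regions, genes, promoter_len, distal_len)
    target = RegionSet([r for r, g in zip(regions, labels) if g in interest])
    background = RegionSet([r for r, g in zip(regions, labels) if g not in interest])
    if len(target) == 0:
        raise ValueError("no region associates with the genes of interest")
    if len(background) == 0:
        raise ValueError("every region associates with the genes of interest; "
                         "background is empty")
    for m in motif_set:
        if m.threshold is None:
            threshold_for_fpr(m, fpr)
    return _fisher_rows(target, background, genome_fasta, motif_set)


def enrich_promoters(
    gene_ids: Sequence[str],
    genes: GeneSet,
    genome_fasta,
    motif_set: MotifSet,
    promoter_len: int = 1000,
    fpr: float = DEFAULT_FPR,
    chrom_table: ChromTable | None = None,
) -> list[EnrichmentRow]:
    """Enrichment in promoters of listed genes vs promoters of all others."""
    listed = set(gene_ids)
    known = [g for g in genes if g.name in listed]
    if not known:
        raise ValueError("none of the listed genes is known")
    others = [g for g in genes if g.name not in listed]
    if not others:
        raise ValueError("no background: the gene list covers every known gene")
    target = RegionSet([promoter_region(g, promoter_len, chrom_table) for g in known])
    background = RegionSet(
        [promoter_region(g, promoter_len, chrom_table) for g in others]
    )
    for m in motif_set:
        if m.threshold is None:
            threshold_for_fpr(m, fpr)
    return _fisher_rows(target, background, genome_fasta, motif_set)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "motif", "target_hits", "target_misses", "background_hits",
    "background_misses", "odds_ratio", "p_value", "adjusted_p",
]


def report(
    rows: Sequence[EnrichmentRow],
    html_path: str | os.PathLike,
    tsv_path: str | os.PathLike | None = None,
) -> None:
    """Write the enrichment table as a sortable HTML page plus a TSV twin."""
    import pandas as pd

    recs = [r.to_dict() for r in rows]
    df = pd.DataFrame.from_records(recs, columns=_TSV_COLUMNS)
    if tsv_path is None:
        base, _ = os.path.splitext(os.fspath(html_path))
        tsv_path = base + ".tsv"
    df.to_csv(tsv_path, sep="\t", index=False)

    head = "".join(
        f'<th onclick="sortBy({i})">{_html.escape(c)}</th>'
        for i, c in enumerate(_TSV_COLUMNS)
    )
    body = "".join(
        "<tr>" + "".join(f"<td>{_html.escape(str(rec[c]))}</td>" for c in _TSV_COLUMNS) + "</tr>"
        for rec in recs
    )
    page = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Motif enrichment</title>
<style>
table {{ border-collapse: collapse; font-family: sans-serif; }}
th, td {{ border: 1px solid #999; padding: 4px 8px; }}
th {{ cursor: pointer; background: #eee; }}
</style>
<script>
function sortBy(col) {{
  const tb = document.querySelector('tbody');
  const rows = Array.from(tb.rows);
  rows.sort((x, y) => {{
    const a = x.cells[col].innerText, b = y.cells[col].innerText;
    const na = parseFloat(a), nb = parseFloat(b);
    if (!isNaN(na) && !isNaN(nb)) return na - nb;
    return a.localeCompare(b);
  }});
  rows.forEach(r => tb.appendChild(r));
}}
</script></head>
<body><h1>Motif enrichment</h1>
<table><thead><tr>{head}</tr></thead><tbody>{body}</tbody></table>
</body></html>
"""
    with open(html_path, "w") as fh:
        fh.write(page)


def read_report_tsv(path: str | os.PathLike) -> list[EnrichmentRow]:
    """Re-parse a report TSV into EnrichmentRow objects."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    rows = []
    for rec in df.to_dict(orient="records"):
        rows.append(
            EnrichmentRow(
                str(rec["motif"]),
                int(rec["target_hits"]),
                int(rec["target_misses"]),
                int(rec["background_hits"]),
                int(rec["background_misses"]),
                float(rec["odds_ratio"]),
                float(rec["p_value"]),
                float(rec["adjusted_p"]),
            )
        )
    return rows
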