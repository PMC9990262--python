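"""Region-vs-region association statistics.

Four tests answering "are these two (or more) sets of genomic intervals
associated beyond chance?":

* **Projection test** — binomial: does the fraction of query regions hitting
  the reference exceed the reference's genomic coverage fraction q?
* **Intersection test** — permutation: is the observed overlap count higher
  than under random relabelling of the pooled regions?  The null keeps every
  region where it is and only shuffles which set it belongs to.
* **Combinatorial test** — Pearson chi-squared of homogeneity on the
  references x queries overlap-count table.
* **Jaccard test** — permutation on the base-pair Jaccard index, with a
  positional null: the second set is relocated uniformly on the genome
  (same region count and length distribution) each round.

The two permutation tests deliberately use different nulls: relabelling
preserves the joint positional structure of the pool, relocation destroys
it.  Empirical p-values always use the add-one rule
p = (1 + #{null >= observed}) / (1 + n_perm), so p >= 1/(n_perm+1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import ChromTable
from .regions import RegionSet, random_regions

__all__ = [
    "TestResult",
    "NullConfig",
    "projection_test",
    "intersection_test",
    "combinatorial_test",
    "jaccard_test",
]


@dataclass
class NullConfig:
    """Permutation-null settings: number of permutations and RNG seed."""

    n_perm: int = 199
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class TestResult:
    """Uniform output of all association tests."""

    test_name: str
    statistic: float
    observed: float
    expected_null: dict
    p_value: float
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        d = {
            "test": self.test_name,
            "statistic": self.statistic,
            "observed": self.observed,
            "p_value": self.p_value,
        }
        d.update({f"null_{k}": v for k, v in self.expected_null.items()})
        d.update(self.extras)
        return d


def _empirical_p(null: np.ndarray, observed: float) -> float:
    return (1.0 + int(np.sum(null >= observed))) / (1.0 + len(null))


def projection_test(
    reference: RegionSet, query: RegionSet, chrom_table: ChromTable
) -> TestResult:
    """Binomial test of query overlap rate against reference genome coverage.

    q = covered_bp(reference) / genome_bp, n = |query|, k = number of query
    regions with >=1 bp overlap with the reference;
    p = P(X >= k), X ~ Binomial(n, q), upper tail.
    """
    if len(reference) == 0 or len(query) == 0:
        raise ValueError("projection test needs nonempty reference and query")
    genome_bp = chrom_table.total_bp
    if genome_bp <= 0:
        raise ValueError("empty genome")
    q = reference.total_bp() / genome_bp
    n = len(query)
    k = query.intersect(reference, mode="count")
    p = float(stats.binom.sf(k - 1, n, q))  # P(X >= k)
    return TestResult(
        "projection",
        statistic=float(k),
        observed=float(k),
        expected_null={"mean": n * q},
        p_value=min(1.0, p),
        extras={"q": q, "k": k, "n": n},
    )


def intersection_test(
    a: RegionSet, b: RegionSet, null: NullConfig
) -> TestResult:
    """Permutation test on the overlap count with a label-shuffling null.

    Observed statistic: number of a-regions with >=1 bp overlap with b.
    Null: pool a and b, randomly repartition into pseudo-sets of the original
    sizes (without replacement), recount.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("intersection test needs nonempty inputs")
    observed = a.intersect(b, mode="count")
    pool = list(a.regions) + list(b.regions)
    rng = np.random.default_rng(null.seed)
    n_a = len(a)
    null_counts = np.empty(null.n_perm)
    for i in range(null.n_perm):
        order = rng.permutation(len(pool))
        pa = RegionSet([pool[j] for j in order[:n_a]])
        pb = RegionSet([pool[j] for j in order[n_a:]])
        null_counts[i] = pa.intersect(pb, mode="count")
    p = _empirical_p(null_counts, observed)
    return TestResult(
        "intersection",
        statistic=float(observed),
        observed=float(observed),
        expected_null={
            "mean": float(null_counts.mean()),
            "sd": float(null_counts.std(ddof=1)) if null.n_perm > 1 else 0.0,
            "n": null.n_perm,
        },
        p_value=p,
        extras={"n_a": len(a), "n_b": len(b)},
    )


def combinatorial_test(
    references: list[RegionSet], queries: list[RegionSet]
) -> TestResult:
    """Chi-squared homogeneity test on the references x queries count table.

    C[i][j] = number of regions of queries[j] overlapping references[i].
    A region overlapping several references counts toward each (plain
    contingency counting, no exclusivity).  All-zero rows/columns are dropped
    with a warning and the degrees of freedom recomputed.
    """
    if len(references) < 2 or len(queries) < 2:
        raise ValueError("combinatorial test needs >=2 references and >=2 queries")
    table = np.array(
        [[q.intersect(ref, mode="count") for q in queries] for ref in references],
        dtype=float,
    )
    keep_rows = table.sum(axis=1) > 0
    keep_cols = table.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        warnings.warn(
            "combinatorial test: dropping all-zero rows/columns", stacklevel=2
        )
        table = table[keep_rows][:, keep_cols]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("fewer than 2 nonzero rows or columns")
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    return TestResult(
        "combinatorial",
        statistic=float(chi2),
        observed=float(chi2),
        expected_null={"dof": int(dof)},
        p_value=float(p),
        extras={
            "dof": int(dof),
            "table": table.astype(int).tolist(),
        },
    )


def jaccard_test(
    a: RegionSet, b: RegionSet, chrom_table: ChromTable, null: NullConfig
) -> TestResult:
    """Permutation test on the base-pair Jaccard index with a positional null.

    J = intersecting bp / union bp.  Each null round relocates b uniformly on
    the genome (same count, lengths resampled from b's lengths) and
    recomputes J.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("Jaccard test needs nonempty inputs")

    def jaccard(x: RegionSet, y: RegionSet) -> float:
        union_bp = x.union(y).total_bp()
        if union_bp == 0:
            return 0.0
        return x.intersect(y, mode="overlap").total_bp() / union_bp

    observed = jaccard(a, b)
    rng = np.random.default_rng(null.seed)
    lengths = b.lengths()
    null_j = np.empty(null.n_perm)
    for i in range(null.n_perm):
        rb = random_regions(chrom_table, lengths, len(b), rng)
        null_j[i] = jaccard(a, rb)
    p = _empirical_p(null_j, observed)
    return TestResult(
        "jaccard",
        statistic=observed,
        observed=observed,
        expected_null={
            "mean": float(null_j.mean()),
            "sd": float(null_j.std(ddof=1)) if null.n_perm > 1 else 0.0,
            "n": null.n_perm,
        },
        p_value=p,
        extras={"jaccard": observed},
    )
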