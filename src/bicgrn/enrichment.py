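"""GO-term enrichment of biclusters and biclustering-comparison metrics.

A bicluster is called enriched at significance level alpha when at least one
annotation term has a one-sided hypergeometric upper-tail p-value below
alpha.  Algorithms are compared by the percentage of enriched biclusters
across a sweep of significance levels, optionally restricted to biclusters
in which at least half the genes carry any annotation, and by their
capacity to recover selected terms (the largest per-bicluster count of
genes annotated to each target term).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from scipy.stats import hypergeom

from .bicluster import Bicluster, BiclusterSet

__all__ = [
    "AnnotationMap",
    "EnrichmentResult",
    "ComparisonReport",
    "read_annotations",
    "hypergeom_pvalue",
    "enrich_bicluster",
    "percent_enriched",
    "pattern_recovery",
    "write_comparison_tsv",
]


@dataclass
class AnnotationMap:
    """Gene -> term annotations over a background population."""

    gene_to_terms: dict[str, set[str]]
    term_to_genes: dict[str, set[str]]
    population: set[str]

    @classmethod
    def from_pairs(cls, pairs, population) -> "AnnotationMap":
        """Build from (gene, term) pairs, dropping genes outside the population."""
        population = set(population)
        g2t: dict[str, set[str]] = {}
        t2g: dict[str, set[str]] = {}
        ignored = 0
        for gene, term in pairs:
            if gene not in population:
                ignored += 1
                continue
            g2t.setdefault(gene, set()).add(term)
            t2g.setdefault(term, set()).add(gene)
        if ignored:
            warnings.warn(f"{ignored} annotation pairs outside the population ignored",
                          stacklevel=2)
        return cls(g2t, t2g, population)

    def __post_init__(self) -> None:
        for gene, terms in self.gene_to_terms.items():
            if gene not in self.population:
                raise ValueError(f"annotated gene {gene!r} not in population")
            for t in terms:
                if gene not in self.term_to_genes.get(t, set()):
                    raise ValueError("gene_to_terms / term_to_genes inconsistent")
        for t, genes in self.term_to_genes.items():
            for g in genes:
                if t not in self.gene_to_terms.get(g, set()):
                    raise ValueError("gene_to_terms / term_to_genes inconsistent")

    @property
    def annotated_genes(self) -> set[str]:
        return set(self.gene_to_terms)


def read_annotations(path, population) -> AnnotationMap:
    """Read gene->term annotations from 2-column TSV or GAF 2.x.

    GAF is detected by the "!gaf-version" pragma or a >= 15 column body;
    columns 2 (DB object symbol) and 5 (GO ID) are used, and rows whose
    qualifier contains NOT are skipped.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        lines = fh.readlines()
    is_gaf = any(ln.lower().startswith("!gaf") for ln in lines[:5])
    if not is_gaf:
        for ln in lines:
            if ln.strip() and not ln.startswith(("!", "#")):
                is_gaf = len(ln.rstrip("\n").split("\t")) >= 15
                break
    pairs = []
    for lineno, ln in enumerate(lines, start=1):
        ln = ln.rstrip("\n")
        if not ln.strip() or ln.startswith(("!", "#")):
            continue
        cols = ln.split("\t")
        if is_gaf:
            if len(cols) < 15:
                raise ValueError(f"{path}: line {lineno}: GAF row with {len(cols)} columns")
            if "NOT" in cols[3].split("|"):
                continue
            pairs.append((cols[2], cols[4]))
        else:
            if len(cols) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns, got {len(cols)}")
            pairs.append((cols[0], cols[1]))
    return AnnotationMap.from_pairs(pairs, population)


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    k = annotated genes in the bicluster, n = bicluster genes in the
    population, K = term genes in the population, N = population size.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"invalid hypergeometric arguments k={k} n={n} K={K} N={N}")
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


@dataclass
class EnrichmentResult:
    bicluster_index: int
    term: str
    k: int
    n: int
    K: int
    N: int
    p_value: float


def enrich_bicluster(b: Bicluster, a: AnnotationMap, alpha: float = 0.05,
                     bicluster_index: int = 0,
                     bonferroni: bool = False) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of every term annotating >= 1 bicluster gene.

    Only genes inside the annotation population count toward n and k.
    Results are sorted by ascending p-value, ties broken by term ID.  With
    ``bonferroni=True`` p-values are multiplied by the number of tested
    terms (capped at 1).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    in_pop = b.gene_set & a.population
    if not in_pop:
        warnings.warn("bicluster disjoint from the annotation population", stacklevel=2)
        return []
    n = len(in_pop)
    N = len(a.population)
    results = []
    terms = {t for g in in_pop for t in a.gene_to_terms.get(g, ())}
    for term in terms:
        term_genes = a.term_to_genes[term]
        k = len(in_pop & term_genes)
        K = len(term_genes)
        p = hypergeom_pvalue(k, n, K, N)
        results.append(EnrichmentResult(bicluster_index, term, k, n, K, N, p))
    if bonferroni and results:
        m = len(results)
        for r in results:
            r.p_value = min(1.0, r.p_value * m)
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


@dataclass
class ComparisonReport:
    """Percent-enriched sweep per algorithm, plus optional pattern-recovery table."""

    percentages: dict[str, list[tuple[float, float]]]  # algorithm -> [(alpha, pct)]
    filtered: bool
    pattern_table: dict[str, dict[str, int]] = field(default_factory=dict)


def _min_pvalue(b: Bicluster, a: AnnotationMap) -> float:
    results = enrich_bicluster(b, a) if (b.gene_set & a.population) else []
    return results[0].p_value if results else 1.0


def percent_enriched(sets: dict[str, BiclusterSet], a: AnnotationMap,
                     levels: list[float], filtered: bool = False) -> ComparisonReport:
    """Percentage of enriched biclusters per algorithm at each level.

    With ``filtered=True`` a bicluster only counts as enriched when at
    least half of its genes carry at least one annotation (the restricted
    comparison criterion).
    """
    if not levels or any(not 0 < lv < 1 for lv in levels):
        raise ValueError("levels must be non-empty with each alpha in (0, 1)")
    report: dict[str, list[tuple[float, float]]] = {}
    for algo, bset in sets.items():
        if len(bset) == 0:
            warnings.warn(f"{algo}: empty bicluster set; reporting 0%", stacklevel=2)
            report[algo] = [(lv, 0.0) for lv in levels]
            continue
        min_ps = []
        passes_filter = []
        for b in bset:
            min_ps.append(_min_pvalue(b, a))
            annotated = sum(1 for g in b.genes if g in a.gene_to_terms)
            passes_filter.append(annotated * 2 >= len(b.genes))
        rows = []
        for lv in levels:
            num = sum(
                1
                for p, ok in zip(min_ps, passes_filter)
                if p < lv and (ok or not filtered)
            )
            rows.append((lv, 100.0 * num / len(bset)))
        report[algo] = rows
    return ComparisonReport(report, filtered)


def pattern_recovery(sets: dict[str, BiclusterSet], a: AnnotationMap,
                     target_terms: list[str]) -> dict[str, dict[str, int]]:
    """Max per-bicluster count of genes annotated to each target term.

    For every algorithm x term, the maximum over the algorithm's biclusters
    of |bicluster genes annotated to the term|; maxima below 2 are floored
    to 0 (isolated single-gene hits carry no pattern signal).
    """
    for t in target_terms:
        if t not in a.term_to_genes:
            raise KeyError(f"unknown term {t!r}")
    table: dict[str, dict[str, int]] = {}
    for algo, bset in sets.items():
        row: dict[str, int] = {}
        for term in target_terms:
            term_genes = a.term_to_genes[term]
            best = 0
            for b in bset:
                best = max(best, len(b.gene_set & term_genes))
            row[term] = best if best >= 2 else 0
        table[algo] = row
    return table


def write_comparison_tsv(report: ComparisonReport, path) -> None:
    """Write the percent-enriched sweep as TSV (algorithm, alpha, percent, filtered)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("algorithm\talpha\tpercent_enriched\tfiltered\n")
        for algo in sorted(report.percentages):
            for alpha, pct in report.percentages[algo]:
                fh.write(f"{algo}\t{alpha:g}\t{pct:.2f}\t{int(report.filtered)}\n")
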