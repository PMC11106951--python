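"""Overrepresentation statistics and qPCR relative quantification.

One-sided (upper-tail) Fisher's exact test of a gene set against term->gene
maps, Benjamini-Hochberg FDR adjustment across all tested terms, and the
2^-ddCt method for qPCR fold changes against a reference gene and a
calibrator sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentResult:
    """Hypergeometric table and test results for one term.

    k = set genes in the term, K = term size in the universe, n = set size,
    N = universe size; p is the one-sided Fisher p, q the BH-adjusted p.
    """

    term: str
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float


@dataclass
class QpcrRecord:
    """Triplicate Ct values for one target gene in one sample."""

    sample: str
    target_gene: str
    ct_triplicate: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(ct <= 0 for ct in self.ct_triplicate):
            raise ValueError("Ct values must be positive")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.ct_triplicate))


def fisher_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail Fisher p: P(X >= k) for X ~ Hypergeom(N, K, n)."""
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent table: k={k}, K={K}, n={n}")
    if K > N or n > N:
        raise ValueError(f"inconsistent table: K={K}, n={n} exceed N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def enrich(
    gene_set: set[str],
    term_map: dict[str, set[str]],
    universe: set[str],
    p_max: float = 0.05,
    q_max: float = 0.05,
) -> list[EnrichmentResult]:
    """Overrepresented terms for a gene set, BH-corrected then filtered.

    Terms are intersected with the universe; every term with members in the
    universe is tested and enters the BH correction, but only terms with
    k >= 1, p <= p_max and q <= q_max are returned, sorted by p ascending.
    """
    if not universe:
        raise ValueError("universe is empty")
    extra = gene_set - universe
    if extra:
        raise ValueError(f"gene set contains genes outside the universe: "
                         f"{sorted(extra)[:5]}")
    N = len(universe)
    n = len(gene_set)
    rows = []
    for term, members in term_map.items():
        members_u = members & universe
        if not members_u:
            continue
        K = len(members_u)
        k = len(gene_set & members_u)
        rows.append((term, k, K, fisher_upper(k, K, n, N)))
    if not rows:
        return []
    qvals = bh_adjust([r[3] for r in rows])
    results = [
        EnrichmentResult(term, k, K, n, N, p, float(q))
        for (term, k, K, p), q in zip(rows, qvals)
        if k >= 1 and p <= p_max and q <= q_max
    ]
    results.sort(key=lambda r: (r.p, r.term))
    return results


def ddct(
    records: list[QpcrRecord],
    reference_gene: str,
    calibrator_sample: str,
) -> pd.DataFrame:
    """2^-ddCt relative fold change per target gene per sample.

    dCt = mean target Ct - mean reference-gene Ct (per sample);
    ddCt = dCt(sample) - dCt(calibrator); fold = 2^-ddCt.
    """
    by_sample: dict[str, dict[str, float]] = {}
    for rec in records:
        by_sample.setdefault(rec.sample, {})[rec.target_gene] = rec.mean_ct
    for sample, genes in by_sample.items():
        if reference_gene not in genes:
            raise ValueError(f"sample {sample} lacks reference gene "
                             f"{reference_gene}")
    if calibrator_sample not in by_sample:
        raise ValueError(f"calibrator sample {calibrator_sample} missing")

    targets = sorted(
        {g for genes in by_sample.values() for g in genes if g != reference_gene}
    )
    cal = by_sample[calibrator_sample]
    rows = []
    for sample, genes in by_sample.items():
        for target in targets:
            if target not in genes:
                continue
            if target not in cal:
                raise ValueError(
                    f"calibrator lacks target gene {target}"
                )
            dct = genes[target] - genes[reference_gene]
            dct_cal = cal[target] - cal[reference_gene]
            fold = 2.0 ** (-(dct - dct_cal))
            rows.append({"sample": sample, "target_gene": target,
                         "delta_ct": dct, "delta_delta_ct": dct - dct_cal,
                         "fold_change": fold})
    return pd.DataFrame(rows)
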