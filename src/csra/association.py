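"""One-sided exact association between panel mutation status and resistance.

The null model is hypergeometric: condition on the table margins (cohort
size N, total resistant K, number of Mut+ specimens n) and let X be the
resistant count among Mut+ specimens.  The upper tail P(X >= observed)
tests enrichment of resistance among mutated specimens, the lower tail
P(X <= observed) tests depletion, and the ``auto`` rule reports the smaller
of the two with its tail label — the one-sided test in the direction of the
observed deviation.

Tables are stratified by histotype (UPS, SS) and pooled (STS); specimens
lacking an assay call for a drug are dropped pairwise from that drug's
tables.  Two follow-up analyses are provided: reassignment of specimens
whose only qualifying variants are partial loss-of-function (they move to
the Mut- arm, or are excluded), and the histotype distribution of TP53
versus other panel-gene mutations among mutated specimens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import DomainError
from .plates import RESISTANT, SENSITIVE
from .variants import (
    GenePanel,
    VariantRecord,
    build_mutation_matrix,
    mutation_status,
    qualifying_variants,
)

STRATA = ("UPS", "SS", "STS")


# log-factorial lookup, grown on demand; integer indexing is far cheaper
# than re-evaluating gammaln on large broadcast tensors
_LOG_FACT = gammaln(np.arange(512) + 1.0)


def _log_fact(n: np.ndarray) -> np.ndarray:
    global _LOG_FACT
    top = int(n.max(initial=0))
    if top >= _LOG_FACT.size:
        _LOG_FACT = gammaln(np.arange(2 * top + 1) + 1.0)
    return _LOG_FACT[n]


def hypergeom_pmf(k, N, K, n):
    """Hypergeometric pmf C(K,k) C(N-K,n-k) / C(N,n), in log space.

    All arguments broadcast; values of ``k`` outside the support yield 0.
    Margins must be integral counts with 0 <= K <= N and 0 <= n <= N.
    """
    N = np.asarray(N)
    K = np.asarray(K)
    n = np.asarray(n)
    if np.any((K < 0) | (K > N) | (n < 0) | (n > N)) or any(
        not np.issubdtype(a.dtype, np.integer) and np.any(a != np.floor(a))
        for a in (N, K, n)
    ):
        raise DomainError(f"invalid hypergeometric margins N={N}, K={K}, n={n}")
    k = np.asarray(k)
    k, N, K, n = np.broadcast_arrays(k, N, K, n)
    in_support = (k >= np.maximum(0, n + K - N)) & (k <= np.minimum(n, K)) & (k == np.floor(k))
    kk = np.where(in_support, k, 0).astype(np.int64)
    Ni = N.astype(np.int64)
    Ki = K.astype(np.int64)
    ni = n.astype(np.int64)
    logp = (
        _log_fact(Ki) - _log_fact(kk) - _log_fact(Ki - kk)
        + _log_fact(Ni - Ki) - _log_fact(ni - kk) - _log_fact(Ni - Ki - ni + kk)
        - (_log_fact(Ni) - _log_fact(ni) - _log_fact(Ni - ni))
    )
    pmf = np.where(in_support, np.exp(logp), 0.0)
    return float(pmf) if pmf.ndim == 0 else pmf


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows {Mut+, Mut-} and columns {sensitive, resistant}."""

    a: int  # Mut+ sensitive
    b: int  # Mut+ resistant
    c: int  # Mut- sensitive
    d: int  # Mut- resistant

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DomainError("contingency counts must be non-negative")
        if self.n == 0:
            raise DomainError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_mut(self) -> int:
        return self.a + self.b

    @property
    def n_resistant(self) -> int:
        return self.b + self.d


@dataclass
class AssociationResult:
    drug: str
    stratum: str
    table: ContingencyTable2x2 | None
    p_one_sided: float
    tail: str  # "upper" | "lower"
    n_evaluable: int
    flags: list[str] = field(default_factory=list)

    @property
    def is_na(self) -> bool:
        return "na" in self.flags


def fisher_one_sided(
    table: ContingencyTable2x2, tail: str = "auto"
) -> tuple[float, str, list[str]]:
    """One-sided Fisher exact p for resistance given Mut+ status.

    Returns ``(p, tail_used, flags)``.  With a degenerate Mut+ or Mut-
    margin the test carries no information and p = 1.0 is returned with a
    ``degenerate-margin`` flag.
    """
    if tail not in ("upper", "lower", "auto"):
        raise ValueError(f"unknown tail {tail!r}")
    flags: list[str] = []
    if table.n_mut == 0 or table.n_mut == table.n:
        return 1.0, ("upper" if tail == "auto" else tail), ["degenerate-margin"]
    N, K, n, x = table.n, table.n_resistant, table.n_mut, table.b
    support = np.arange(max(0, n + K - N), min(n, K) + 1)
    pmf = hypergeom_pmf(support, N, K, n)
    upper = float(pmf[support >= x].sum())
    lower = float(pmf[support <= x].sum())
    if tail == "upper":
        return min(upper, 1.0), "upper", flags
    if tail == "lower":
        return min(lower, 1.0), "lower", flags
    if upper <= lower:
        return min(upper, 1.0), "upper", flags
    return min(lower, 1.0), "lower", flags


def make_table(
    mut_status: Mapping[str, bool], calls: Mapping[str, str]
) -> ContingencyTable2x2:
    """Cross-tabulate mutation status against sensitive/resistant calls.

    ``calls`` maps specimen -> call; only specimens present in both inputs
    with a non-NA call contribute (pairwise deletion).
    """
    a = b = c = d = 0
    for spec_id, call in calls.items():
        if spec_id not in mut_status or call not in (SENSITIVE, RESISTANT):
            continue
        if mut_status[spec_id]:
            if call == SENSITIVE:
                a += 1
            else:
                b += 1
        else:
            if call == SENSITIVE:
                c += 1
            else:
                d += 1
    return ContingencyTable2x2(a, b, c, d)


def _calls_for(calls: pd.DataFrame, drug: str, specimens: Sequence[str]) -> dict[str, str]:
    sub = calls[(calls["drug"] == drug) & (calls["specimen_id"].isin(specimens))]
    return dict(zip(sub["specimen_id"], sub["call"]))


def stratified_association(
    mut_status: pd.Series,
    calls: pd.DataFrame,
    annotations: pd.DataFrame,
    drugs: Sequence[str] | None = None,
    tail: str = "auto",
) -> list[AssociationResult]:
    """Per-drug, per-stratum one-sided exact tests (the headline grid).

    ``mut_status``: boolean Series indexed by specimen_id (row-wise OR of
    the mutation matrix).  ``calls``: long table (specimen_id, drug, call)
    where call is "sensitive", "resistant" or "NA".  ``annotations``:
    (specimen_id, histotype) with histotype in {UPS, SS}.
    """
    if drugs is None:
        drugs = list(dict.fromkeys(calls["drug"]))
    by_stratum = {
        "UPS": annotations.loc[annotations["histotype"] == "UPS", "specimen_id"].tolist(),
        "SS": annotations.loc[annotations["histotype"] == "SS", "specimen_id"].tolist(),
        "STS": annotations["specimen_id"].tolist(),
    }
    status = {str(k): bool(v) for k, v in mut_status.items()}
    results = []
    for drug in drugs:
        for stratum in STRATA:
            drug_calls = _calls_for(calls, drug, by_stratum[stratum])
            evaluable = {
                s: c for s, c in drug_calls.items() if c in (SENSITIVE, RESISTANT)
            }
            if not evaluable:
                results.append(
                    AssociationResult(drug, stratum, None, float("nan"), "", 0, ["na"])
                )
                continue
            table = make_table(status, evaluable)
            p, used_tail, flags = fisher_one_sided(table, tail=tail)
            results.append(
                AssociationResult(drug, stratum, table, p, used_tail, table.n, flags)
            )
    return results


def association_grid(results: Iterable[AssociationResult]) -> pd.DataFrame:
    """Drug x stratum grid of counts and p-values (publication layout)."""
    rows = []
    for r in results:
        rows.append(
            {
                "drug": r.drug,
                "stratum": r.stratum,
                "mut_sensitive": r.table.a if r.table else None,
                "mut_resistant": r.table.b if r.table else None,
                "nomut_sensitive": r.table.c if r.table else None,
                "nomut_resistant": r.table.d if r.table else None,
                "n_evaluable": r.n_evaluable,
                "p_one_sided": r.p_one_sided,
                "tail": r.tail,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows)


def add_bh_adjusted(grid: pd.DataFrame) -> pd.DataFrame:
    """Append a Benjamini-Hochberg column (off the default path)."""
    out = grid.copy()
    p = out["p_one_sided"].to_numpy(dtype=float)
    ok = np.isfinite(p)
    adj = np.full_like(p, np.nan)
    if ok.sum():
        m = int(ok.sum())
        order = np.argsort(p[ok])
        ranked = p[ok][order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        vals = np.empty(m)
        vals[order] = np.minimum(ranked, 1.0)
        adj[ok] = vals
    out["p_bh"] = adj
    return out


def reassignment_analysis(
    variants: Sequence[VariantRecord],
    panel: GenePanel,
    calls: pd.DataFrame,
    annotations: pd.DataFrame,
    drug: str = "Dox",
    policy: str = "reassign",
    tail: str = "auto",
) -> tuple[AssociationResult, AssociationResult]:
    """Partial loss-of-function sensitivity analysis for one drug.

    Specimens whose qualifying panel variants are *all* annotated
    ``lof_class == "partial"`` retain some pathway function and are either
    moved to the Mut- arm (``policy="reassign"``) or dropped from the table
    (``policy="exclude"``).  Returns (baseline, adjusted) pooled-cohort
    results; with no partial-LOF specimens the adjusted result equals the
    baseline and carries a ``no-partial-lof`` flag.
    """
    if policy not in ("reassign", "exclude"):
        raise ValueError(f"unknown policy {policy!r}")
    cohort = annotations["specimen_id"].tolist()
    matrix = build_mutation_matrix(variants, panel, cohort)
    status = mutation_status(matrix)
    qualified = qualifying_variants(variants, panel)
    partial_only = set()
    for spec_id in status.index[status]:
        mine = [v for v in qualified if v.specimen_id == spec_id]
        if mine and all(v.lof_class == "partial" for v in mine):
            partial_only.add(spec_id)

    drug_calls = _calls_for(calls, drug, cohort)
    evaluable = {s: c for s, c in drug_calls.items() if c in (SENSITIVE, RESISTANT)}
    base_table = make_table(dict(status), evaluable)
    p, used_tail, flags = fisher_one_sided(base_table, tail=tail)
    baseline = AssociationResult(drug, "STS", base_table, p, used_tail, base_table.n, flags)

    adj_status = {s: (False if s in partial_only else bool(v)) for s, v in status.items()}
    adj_calls = dict(evaluable)
    if policy == "exclude":
        for s in partial_only:
            adj_calls.pop(s, None)
    adj_table = make_table(adj_status, adj_calls)
    p2, tail2, flags2 = fisher_one_sided(adj_table, tail=tail)
    if not partial_only:
        flags2 = flags2 + ["no-partial-lof"]
    adjusted = AssociationResult(drug, "STS", adj_table, p2, tail2, adj_table.n, flags2)
    return baseline, adjusted


def gene_class_distribution_test(
    variants: Sequence[VariantRecord],
    panel: GenePanel,
    annotations: pd.DataFrame,
    gene: str = "TP53",
    tail: str = "auto",
) -> AssociationResult:
    """Histotype distribution of mutations in ``gene`` vs other panel genes.

    Among mutated specimens only, builds the 2x2 with rows {UPS, SS} and
    columns {gene-mutated, other-panel-gene-only} and applies the one-sided
    exact test.  A histotype with zero mutated specimens yields an NA result.
    """
    gene = gene.strip().upper()
    histotype = dict(zip(annotations["specimen_id"], annotations["histotype"]))
    qualified = qualifying_variants(variants, panel)
    per_spec: dict[str, set[str]] = {}
    for v in qualified:
        per_spec.setdefault(v.specimen_id, set()).add(v.gene.strip().upper())
    counts = {("UPS", True): 0, ("UPS", False): 0, ("SS", True): 0, ("SS", False): 0}
    for spec_id, genes in per_spec.items():
        h = histotype.get(spec_id)
        if h in ("UPS", "SS"):
            counts[(h, gene in genes)] += 1
    ups_n = counts[("UPS", True)] + counts[("UPS", False)]
    ss_n = counts[("SS", True)] + counts[("SS", False)]
    if ups_n == 0 or ss_n == 0:
        return AssociationResult(gene, "STS", None, float("nan"), "", ups_n + ss_n, ["na"])
    # reuse the Mut+/Mut- x sensitive/resistant machinery with rows=UPS/SS,
    # columns=gene-mutated/other-only
    table = ContingencyTable2x2(
        a=counts[("UPS", True)],
        b=counts[("UPS", False)],
        c=counts[("SS", True)],
        d=counts[("SS", False)],
    )
    p, used_tail, flags = fisher_one_sided(table, tail=tail)
    return AssociationResult(gene, "STS", table, p, used_tail, table.n, flags)


def exact_power(
    n: int,
    mut_prevalence: float,
    baseline_resistance_prob: float,
    odds_ratio: float,
    alpha: float = 0.05,
    tail: str = "auto",
) -> float:
    """Exact rejection probability of the one-sided test by full enumeration.

    Specimen mutation status is Bernoulli(prevalence); resistance is
    Bernoulli with the baseline probability for Mut- and odds multiplied by
    ``odds_ratio`` for Mut+.  Sums binomial probabilities over all
    (n_mut, resistant among Mut+, resistant among Mut-) outcomes whose
    table rejects at level ``alpha``.
    """
    from scipy.stats import binom

    base_odds = baseline_resistance_prob / (1.0 - baseline_resistance_prob)
    p_mut = base_odds * odds_ratio / (1.0 + base_odds * odds_ratio)
    power = 0.0
    for m in range(n + 1):
        pm = binom.pmf(m, n, mut_prevalence)
        if pm == 0.0:
            continue
        for r_mut in range(m + 1):
            pr1 = binom.pmf(r_mut, m, p_mut)
            for r_neg in range(n - m + 1):
                pr0 = binom.pmf(r_neg, n - m, baseline_resistance_prob)
                table = ContingencyTable2x2(
                    m - r_mut, r_mut, (n - m) - r_neg, r_neg
                )
                p, _, flags = fisher_one_sided(table, tail=tail)
                if p < alpha and "degenerate-margin" not in flags:
                    power += pm * pr1 * pr0
    return power
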