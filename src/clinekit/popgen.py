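"""Supporting population-genetic computations.

Allele frequencies and between-ecotype differentiation from diploid
R-allele dosage panels, F2 recombination / map distance, exact contingency
tests, and coding of flower-color phenotypes into a genotype cline dataset.

F_ST uses the Weir & Cockerham (1984) theta estimator with the two groups
(ecotypes) as subpopulations.  The variance components a, b, c are computed
in exact rational arithmetic over the integer allele and heterozygote
counts, so fixed differences give theta = 1.0 exactly rather than
1 - machine-epsilon.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import product
from math import comb, log

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import ValidationError
from .fitting import ClineDataset, PopulationSample

__all__ = [
    "GenotypePanel",
    "F2CrossCounts",
    "FisherExactResult",
    "allele_frequencies",
    "fst_between_groups",
    "map_distance",
    "fisher_exact",
    "phenotype_to_cline_counts",
    "PHENOTYPE_DOSAGE",
]

#: Flower-color phenotype -> R-allele dosage coding: red is RR, red-orange
#: and orange are the heterozygote RY, yellow is YY.
PHENOTYPE_DOSAGE = {"red": 2, "red-orange": 1, "orange": 1, "yellow": 0}

_META_COLS = ("population", "group")


@dataclass
class GenotypePanel:
    """Individuals x loci diploid R-allele dosages with population/group labels.

    ``data`` is indexed by individual id, with columns ``population``,
    ``group``, and one float column per locus holding dosage 0/1/2 or NaN
    for missing.
    """

    data: pd.DataFrame

    def __post_init__(self):
        for col in _META_COLS:
            if col not in self.data.columns:
                raise ValidationError(f"genotype panel is missing required column {col!r}")
        for locus in self.loci:
            vals = self.data[locus].dropna()
            if not vals.isin([0, 1, 2]).all():
                raise ValidationError(f"locus {locus!r} has dosages outside {{0, 1, 2, missing}}")

    @property
    def loci(self) -> tuple:
        return tuple(c for c in self.data.columns if c not in _META_COLS)

    @property
    def groups(self) -> tuple:
        return tuple(pd.unique(self.data["group"].dropna()))

    @classmethod
    def from_records(cls, records) -> "GenotypePanel":
        """Build from (id, population, group, {locus: dosage-or-None}) tuples."""
        rows = {}
        for ind_id, pop, group, dosages in records:
            rows[ind_id] = {"population": pop, "group": group, **dosages}
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "id"
        return cls(df)

    @classmethod
    def from_tsv(cls, path) -> "GenotypePanel":
        """Read a TSV with columns id, population, group, then one column per
        locus coded RR/RY/YY or 0/1/2 (empty/NA = missing)."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"id", "population", "group"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"genotype TSV is missing columns: {sorted(missing)}")
        df = df.set_index("id")
        geno_map = {"RR": 2.0, "RY": 1.0, "YR": 1.0, "YY": 0.0, "0": 0.0, "1": 1.0, "2": 2.0}
        out = df[["population", "group"]].copy()
        for locus in (c for c in df.columns if c not in _META_COLS):
            raw = df[locus]
            vals = raw.map(lambda v: np.nan if pd.isna(v) or v == "" else geno_map.get(str(v).strip()))
            bad = raw.notna() & (raw != "") & vals.isna()
            if bad.any():
                raise ValidationError(
                    f"locus {locus!r}: unrecognized genotype codes {sorted(set(raw[bad]))}"
                )
            out[locus] = vals.astype(float)
        return cls(out)


def allele_frequencies(panel: GenotypePanel, by: str = "group") -> pd.DataFrame:
    """R-allele frequency per locus per group: sum(dosage) / (2 * non-missing).

    Missing genotypes are excluded from both numerator and denominator; a
    group with no genotyped individuals at a locus gets NaN, never zero.
    """
    if by not in _META_COLS:
        raise ValidationError(f"'by' must be one of {_META_COLS}")
    loci = list(panel.loci)
    grouped = panel.data.groupby(by, sort=False)[loci]
    freq = grouped.sum(min_count=1) / (2.0 * grouped.count())
    return freq


def _wc_theta_two_groups(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Weir–Cockerham theta for two subpopulations at one biallelic locus.

    Inputs are non-missing dosage arrays.  All components are exact
    Fractions of the integer counts; returns NaN when the locus is
    monomorphic overall (a + b + c = 0).
    """
    n = [len(dosages_a), len(dosages_b)]
    k = [int(dosages_a.sum()), int(dosages_b.sum())]  # R-allele counts
    het = [int((dosages_a == 1).sum()), int((dosages_b == 1).sum())]
    r = 2
    p = [Fraction(k[i], 2 * n[i]) for i in range(r)]
    h = [Fraction(het[i], n[i]) for i in range(r)]

    n_sum = n[0] + n[1]
    nbar = Fraction(n_sum, r)
    nc = (n_sum - Fraction(n[0] ** 2 + n[1] ** 2, n_sum)) / (r - 1)
    pbar = Fraction(n[0] * p[0] + n[1] * p[1], 1) / n_sum
    s2 = (n[0] * (p[0] - pbar) ** 2 + n[1] * (p[1] - pbar) ** 2) / ((r - 1) * nbar)
    hbar = Fraction(n[0] * h[0] + n[1] * h[1], 1) / n_sum

    pq = pbar * (1 - pbar)
    a = (nbar / nc) * (s2 - (pq - s2 * Fraction(r - 1, r) - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pq - s2 * Fraction(r - 1, r) - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2

    denom = a + b + c
    if denom == 0:
        return float("nan")
    return float(a / denom)


def fst_between_groups(panel: GenotypePanel) -> pd.Series:
    """Between-group Weir–Cockerham F_ST (theta) per locus.

    Requires exactly two groups with >= 2 genotyped individuals each at a
    locus; loci monomorphic across both groups are reported NaN.  Theta is
    1 exactly when the two groups are fixed for alternate alleles, and can
    be slightly negative with no differentiation.
    """
    groups = panel.groups
    if len(groups) != 2:
        raise ValidationError(f"exactly two groups are required (found {len(groups)}: {list(groups)})")
    ga = panel.data[panel.data["group"] == groups[0]]
    gb = panel.data[panel.data["group"] == groups[1]]
    out = {}
    for locus in panel.loci:
        da = ga[locus].dropna().to_numpy()
        db = gb[locus].dropna().to_numpy()
        if len(da) < 2 or len(db) < 2:
            raise ValidationError(f"locus {locus!r}: each group needs >= 2 genotyped individuals")
        out[locus] = _wc_theta_two_groups(da, db)
    return pd.Series(out, name="fst")


@dataclass(frozen=True)
class F2CrossCounts:
    """Recombination summary of a two-locus F2 intercross.

    ``n_recombinant`` counts recombinant *gametes* under the
    single-recombinant-gamete convention (a recombinant individual carries
    one; rare double recombinants carry two), so the recombination fraction
    is r = n_recombinant / (2 n_individuals).
    """

    n_individuals: int
    n_recombinant: int

    def __post_init__(self):
        if self.n_individuals < 0:
            raise ValidationError("n_individuals must be non-negative")
        if not (0 <= self.n_recombinant <= 2 * self.n_individuals):
            raise ValidationError("n_recombinant must lie in [0, 2 * n_individuals]")

    @property
    def r(self) -> float:
        if self.n_individuals == 0:
            raise ValidationError("cannot form a recombination fraction from 0 individuals")
        return self.n_recombinant / (2.0 * self.n_individuals)


def map_distance(cross: F2CrossCounts, map_function: str = "direct") -> float:
    """Genetic map distance (cM) from F2 recombinant counts.

    direct: 100 r;  haldane: -50 ln(1 - 2r);  kosambi: 25 ln((1+2r)/(1-2r)).
    The Haldane and Kosambi functions require r < 0.5.
    """
    r = cross.r
    if map_function == "direct":
        return 100.0 * r
    if map_function in ("haldane", "kosambi"):
        if r >= 0.5:
            raise ValidationError(
                f"{map_function} map function requires recombination fraction r < 0.5 (got r={r:.4g})"
            )
        if map_function == "haldane":
            return -50.0 * log(1.0 - 2.0 * r)
        return 25.0 * log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    raise ValidationError("map_function must be one of: direct, haldane, kosambi")


@dataclass(frozen=True)
class FisherExactResult:
    p_value: float
    method: str  # "enumeration" or "monte-carlo"
    n_resamples: int = 0
    degenerate: bool = False  # a zero margin: p = 1 by convention


def _log_point_prob(row1, col_sums, log_denom):
    # multivariate hypergeometric point log-probability given fixed margins
    lp = -log_denom
    for a, cj in zip(row1, col_sums):
        lp += gammaln(cj + 1) - gammaln(a + 1) - gammaln(cj - a + 1)
    return lp


def fisher_exact(
    table,
    *,
    seed: int = 0,
    max_support: int = 1_000_000,
    n_resamples: int = 100_000,
) -> FisherExactResult:
    """Two-sided exact test of independence for a 2 x K table (K = 2..4).

    Conditional on the margins, the first row follows a multivariate
    hypergeometric distribution; the two-sided p-value sums the
    probabilities of all outcomes no more probable than the observed one
    (point-probability rule — for 2 x 2 this is the standard two-sided
    Fisher exact test).  When the conditional support exceeds
    ``max_support`` outcomes, a seeded Monte-Carlo estimate with
    ``n_resamples`` resamples is returned instead (p = (1 + #{P <= P_obs})
    / (B + 1)).  A zero row or column margin makes the table degenerate:
    p = 1 with the ``degenerate`` flag set.
    """
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] != 2 or not (2 <= t.shape[1] <= 4):
        raise ValidationError("table must be 2 x K with K in {2, 3, 4}")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.floor(t)):
            raise ValidationError("table entries must be non-negative integers")
        t = t.astype(int)
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    if np.any(row_sums == 0) or np.any(col_sums == 0):
        return FisherExactResult(p_value=1.0, method="degenerate", degenerate=True)

    r1 = int(row_sums[0])
    total = int(t.sum())
    log_denom = gammaln(total + 1) - gammaln(r1 + 1) - gammaln(total - r1 + 1)
    lp_obs = _log_point_prob(t[0], col_sums, log_denom)
    tol = 1e-7

    support_bound = 1
    for cj in col_sums:
        support_bound *= min(int(cj), r1) + 1
    if support_bound <= max_support:
        p = 0.0
        ranges = [range(min(int(cj), r1) + 1) for cj in col_sums[:-1]]
        last_c = int(col_sums[-1])
        for head in product(*ranges):
            rem = r1 - sum(head)
            if 0 <= rem <= last_c:
                lp = _log_point_prob((*head, rem), col_sums, log_denom)
                if lp <= lp_obs + tol:
                    p += np.exp(lp)
        p = min(1.0, float(p))
        if p > 1.0 - 1e-9:  # summed the whole support; absorb rounding
            p = 1.0
        return FisherExactResult(p_value=p, method="enumeration")

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(col_sums, r1, size=n_resamples)
    lps = np.array([_log_point_prob(row, col_sums, log_denom) for row in draws])
    hits = int(np.sum(lps <= lp_obs + tol))
    return FisherExactResult(
        p_value=(1 + hits) / (n_resamples + 1), method="monte-carlo", n_resamples=n_resamples
    )


def phenotype_to_cline_counts(
    phenotypes,
    positions,
    locus: str = "flower_color",
) -> ClineDataset:
    """Code flower-color phenotypes as genotypes and tally them into a
    cline dataset.

    Individuals are coded red -> RR (dosage 2), red-orange / orange -> RY
    (1), yellow -> YY (0); per population k = sum of dosages and n = 2 x
    individuals, yielding a dataset the cline-fitting module consumes
    directly.

    Parameters
    ----------
    phenotypes : iterable of (population_id, category)
        Category must be one of red, red-orange, orange, yellow.
    positions : mapping population_id -> transect position (km)
    """
    tallies = {}
    for pop, category in phenotypes:
        if category not in PHENOTYPE_DOSAGE:
            raise ValidationError(
                f"unrecognized flower-color category {category!r}; "
                f"valid labels: {sorted(PHENOTYPE_DOSAGE)}"
            )
        k, n = tallies.get(pop, (0, 0))
        tallies[pop] = (k + PHENOTYPE_DOSAGE[category], n + 2)
    missing = [pop for pop in tallies if pop not in positions]
    if missing:
        raise ValidationError(f"no transect position given for populations: {sorted(missing)}")
    samples = tuple(
        PopulationSample(population_id=pop, x=float(positions[pop]), n=n, k=k)
        for pop, (k, n) in tallies.items()
    )
    return ClineDataset(locus=locus, samples=samples)
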