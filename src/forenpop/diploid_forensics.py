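"""Forensic efficiency parameters for diploid loci.

Per locus: observed/expected heterozygosity, polymorphism information
content (PIC), match probability (PM) and its complement the power of
discrimination (PD), power of exclusion (PE), typical paternity index
(TPI) and an exact Hardy–Weinberg test; across loci: combined PM/PD/PE
computed in log space.

Conventions: H_exp uses Nei's unbiased estimator (2n/(2n−1))(1 − Σp²);
PM is the sum of squared *observed* genotype frequencies, so PD = 1 − PM
holds exactly; PE is the single-parent exclusion form h²(1 − 2hH²) with
h the observed heterozygosity and H = 1 − h; TPI = 1/(2(1 − h)).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_formats import GenotypeTable, ValidationError


def _typed(genotypes) -> list:
    return [g for g in genotypes if g is not None]


def observed_heterozygosity(genotypes) -> float:
    """Heterozygote fraction among typed diploid genotypes."""
    typed = _typed(genotypes)
    if not typed:
        raise ValidationError("no typed individuals")
    het = sum(1 for g in typed if g[0] != g[1])
    return het / len(typed)


def expected_heterozygosity(freqs: dict, n: int) -> float:
    """Nei's unbiased expected heterozygosity (2n/(2n−1))(1 − Σp²)."""
    if n < 2:
        raise ValidationError("expected heterozygosity needs n >= 2")
    s = sum(p * p for p in freqs.values())
    return (2 * n / (2 * n - 1)) * (1.0 - s)


def pic(freqs: dict) -> float:
    """Polymorphism information content 1 − Σp² − Σ_{i<j} 2 p_i² p_j²."""
    p = list(freqs.values())
    s2 = sum(x * x for x in p)
    cross = 0.0
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            cross += 2.0 * p[i] * p[i] * p[j] * p[j]
    return 1.0 - s2 - cross


def match_probability(genotypes) -> float:
    """Sum of squared observed genotype frequencies."""
    typed = _typed(genotypes)
    if not typed:
        raise ValidationError("no typed individuals")
    n = len(typed)
    counts = Counter(tuple(sorted(g)) for g in typed)
    return sum((c / n) ** 2 for c in counts.values())


def power_of_discrimination(pm: float) -> float:
    if not 0.0 <= pm <= 1.0:
        raise ValidationError("PM must lie in [0, 1]")
    return 1.0 - pm


def power_of_exclusion(h_obs: float) -> float:
    """Single-parent exclusion probability h²(1 − 2hH²), H = 1 − h."""
    if not 0.0 <= h_obs <= 1.0:
        raise ValidationError("H_obs must lie in [0, 1]")
    h = h_obs
    H = 1.0 - h
    return h * h * (1.0 - 2.0 * h * H * H)


def typical_paternity_index(h_obs: float) -> float:
    if not 0.0 <= h_obs <= 1.0:
        raise ValidationError("H_obs must lie in [0, 1]")
    if h_obs == 1.0:
        raise ValidationError("TPI undefined (no homozygotes observed)")
    return 1.0 / (2.0 * (1.0 - h_obs))


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact tests
# ---------------------------------------------------------------------------


def _log_levene(het: int, n: int, n_a: int, n_b: int) -> float:
    """Log P(n_het = het | n individuals, n_a + n_b = 2n allele copies)."""
    n_aa = (n_a - het) // 2
    n_bb = (n_b - het) // 2
    return (
        gammaln(n + 1)
        - gammaln(n_aa + 1)
        - gammaln(het + 1)
        - gammaln(n_bb + 1)
        + het * math.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )


def _biallelic_exact_p(genotype_counts: Counter, n: int) -> float:
    alleles = sorted({a for g in genotype_counts for a in g})
    a, b = alleles
    n_a = sum(c * g.count(a) for g, c in genotype_counts.items())
    n_b = 2 * n - n_a
    het_obs = sum(c for g, c in genotype_counts.items() if g[0] != g[1])
    lp_obs = _log_levene(het_obs, n, n_a, n_b)
    rare = min(n_a, n_b)
    p = 0.0
    for het in range(rare % 2, rare + 1, 2):
        lp = _log_levene(het, n, n_a, n_b)
        if lp <= lp_obs + 1e-12:
            p += math.exp(lp)
    return min(p, 1.0)


def _log_multiallelic_probability(genotype_counts: Counter, n: int) -> float:
    """Log conditional probability of a multiallelic genotype configuration.

    P = n! 2^het Π_i n_i! / ((2n)! Π_{i<=j} n_ij!) given allele counts n_i.
    """
    allele_counts: Counter = Counter()
    het = 0
    lp = gammaln(n + 1)
    for g, c in genotype_counts.items():
        lp -= gammaln(c + 1)
        allele_counts[g[0]] += c
        allele_counts[g[1]] += c
        if g[0] != g[1]:
            het += c
    lp += het * math.log(2.0)
    for cnt in allele_counts.values():
        lp += gammaln(cnt + 1)
    lp -= gammaln(2 * n + 1)
    return lp


def hwe_exact_test(
    genotypes,
    n_perm: int = 100_000,
    seed: "int | None" = None,
    force_monte_carlo: bool = False,
) -> float:
    """Exact Hardy–Weinberg p-value for one diploid locus.

    Biallelic loci: full enumeration of the Levene conditional
    distribution of heterozygote counts — the p-value sums the
    probabilities of all configurations no more probable than the
    observed one. Multiallelic loci: Monte-Carlo exact test by random
    re-pairing of the observed allele pool, with
    p = (1 + #{permuted config log-prob ≤ observed}) / (1 + n_perm).
    A monomorphic locus returns p = 1.
    """
    typed = [tuple(sorted(g)) for g in _typed(genotypes)]
    if not typed:
        raise ValidationError("no typed individuals")
    n = len(typed)
    genotype_counts = Counter(typed)
    alleles = sorted({a for g in typed for a in g})
    if len(alleles) == 1:
        return 1.0
    if len(alleles) == 2 and not force_monte_carlo:
        return _biallelic_exact_p(genotype_counts, n)

    rng = np.random.default_rng(seed)
    pool = np.array([a for g in typed for a in g])
    lp_obs = _log_multiallelic_probability(genotype_counts, n)
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pool)
        perm_counts = Counter(
            tuple(sorted((pool[2 * i], pool[2 * i + 1]))) for i in range(n)
        )
        if _log_multiallelic_probability(perm_counts, n) <= lp_obs + 1e-12:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def bonferroni_adjust(p_values, alpha: float = 0.05) -> list[bool]:
    """Significance flags at the Bonferroni-corrected level alpha / L."""
    p_values = list(p_values)
    if not p_values:
        raise ValidationError("no p-values to adjust")
    cut = alpha / len(p_values)
    return [p < cut for p in p_values]


# ---------------------------------------------------------------------------
# per-locus summaries and combined values
# ---------------------------------------------------------------------------


@dataclass
class CombinedSummary:
    """Multi-locus combined match/discrimination/exclusion values.

    ``cpm`` = Π PM_l; ``cpd`` = 1 − cpm; ``cpe`` = 1 − Π(1 − PE_l).
    The complements are also carried in log space (natural log) because
    at panel scale they underflow doubles only barely and print in the
    conventional "1 − x·10^−k" form.
    """

    n_loci: int
    cpm: float
    cpd: float
    cpe: float
    log_cpm: float
    log_one_minus_cpe: float

    @property
    def cpd_complement(self) -> float:
        """Π PM, i.e. 1 − CPD."""
        return math.exp(self.log_cpm)

    @property
    def cpe_complement(self) -> float:
        """Π (1 − PE), i.e. 1 − CPE."""
        return math.exp(self.log_one_minus_cpe)

    def formatted(self) -> dict:
        return {
            "n_loci": self.n_loci,
            "CPM": f"{self.cpm:.6g}",
            "CPD": format_complement(self.log_cpm),
            "CPE": format_complement(self.log_one_minus_cpe),
        }


def format_complement(log_x: float) -> str:
    """Render 1 − x from log(x) as e.g. "1-3.4332e-11"."""
    if log_x == -math.inf:
        return "1-0"
    log10_x = log_x / math.log(10.0)
    exp10 = math.floor(log10_x)
    mantissa = 10 ** (log10_x - exp10)
    if round(mantissa, 4) >= 10:  # carry
        mantissa /= 10
        exp10 += 1
    return f"1-{mantissa:.4f}e{exp10:+03d}"


def combined_parameters(summaries: pd.DataFrame) -> CombinedSummary:
    """Combine per-locus PM and PE columns into CPM/CPD/CPE.

    Products are accumulated as sums of logs to avoid underflow on large
    SNP panels.
    """
    if len(summaries) < 1:
        raise ValidationError("need at least one locus")
    pm = summaries["PM"].to_numpy(dtype=float)
    pe = summaries["PE"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_cpm = float(np.sum(np.log(pm))) if (pm > 0).all() else -math.inf
        one_minus_pe = 1.0 - pe
        log_cpe_c = (
            float(np.sum(np.log(one_minus_pe)))
            if (one_minus_pe > 0).all()
            else -math.inf
        )
    cpm = math.exp(log_cpm) if log_cpm > -745 else 0.0
    cpe_c = math.exp(log_cpe_c) if log_cpe_c > -745 else 0.0
    return CombinedSummary(
        n_loci=len(summaries),
        cpm=cpm,
        cpd=1.0 - cpm,
        cpe=1.0 - cpe_c,
        log_cpm=log_cpm,
        log_one_minus_cpe=log_cpe_c,
    )


def forensic_summary(
    table: GenotypeTable,
    loci: "list[str] | None" = None,
    n_perm: int = 100_000,
    seed: "int | None" = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-locus forensic parameter table for diploid loci.

    Columns: locus, n, Hobs, Hexp, PIC, PM, PD, PE, TPI, HWE_p,
    significant_after_bonferroni. The Bonferroni batch is the set of
    loci summarized together in this call (per marker-class convention:
    summarize each class in its own call).
    """
    if loci is None:
        loci = [l.name for l in table.loci if l.ploidy_in_males == 2]
    rows = []
    for k, locus in enumerate(loci):
        genos = table.column(locus)
        typed = [g for g in genos if g is not None]
        if not typed:
            raise ValidationError(f"locus {locus!r} has no typed individuals")
        n = len(typed)
        tally: Counter = Counter(a for g in typed for a in g)
        total = sum(tally.values())
        freqs = {a: c / total for a, c in tally.items()}
        h = observed_heterozygosity(genos)
        pm = match_probability(genos)
        locus_seed = None if seed is None else (seed + 7919 * k) % (2**31)
        rows.append(
            {
                "locus": locus,
                "n": n,
                "Hobs": h,
                "Hexp": expected_heterozygosity(freqs, n),
                "PIC": pic(freqs),
                "PM": pm,
                "PD": power_of_discrimination(pm),
                "PE": power_of_exclusion(h),
                "TPI": typical_paternity_index(h) if h < 1 else math.inf,
                "HWE_p": hwe_exact_test(genos, n_perm=n_perm, seed=locus_seed),
            }
        )
    df = pd.DataFrame(rows)
    df["significant_after_bonferroni"] = bonferroni_adjust(df["HWE_p"], alpha=alpha)
    return df
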