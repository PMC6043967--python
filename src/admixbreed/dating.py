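"""Temporal inference from LD and ancestry switches.

Three complementary clocks for a recently admixed breed:

* **LD-based N_E trajectory** — the Sved/Hayes relation
  E(r^2) = 1/(1 + 4 N_E c) + 1/n links mean genotypic r^2 between SNP pairs
  at genetic distance c (Morgans) to the effective population size
  N_E roughly t = 1/(2c) generations ago; 1/n (n = sampled chromosomes)
  corrects for finite sample size.
* **Weighted-LD admixture dating** — the admixture-induced covariance between
  SNP pairs, weighted by the parental allele-frequency contrast, decays as
  exp(-g * d) with distance d for g generations since a pulse of admixture;
  g is fit by nonlinear least squares with a chromosome bootstrap CI.
* **Switch-count dating** — the number S of ancestry junctions along a
  diploid genome of map length L Morgans at admixture fraction q grows with
  generations; the declared form g = 1 + S / (4 L q (1 - q)) inverts it.

Plus the generation <-> calendar-year conversion and the expected
new-variant accumulation p = mu * generations * N_E.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .containers import GeneticMap, GenotypeMatrix
from .qc import pairwise_complete_r2


def sved_expected_r2(ne: float, c, n_chrom: float) -> np.ndarray:
    """E(r^2) = 1/(1 + 4 N_E c) + 1/n."""
    c = np.asarray(c, dtype=float)
    return 1.0 / (1.0 + 4.0 * ne * c) + 1.0 / n_chrom


def invert_sved(r2_mean: float, c: float, n_chrom: float) -> float:
    """Solve the Sved relation for N_E; NaN when r2 <= 1/n (undefined)."""
    adj = r2_mean - 1.0 / n_chrom
    if adj <= 0 or c <= 0:
        return float("nan")
    return (1.0 / adj - 1.0) / (4.0 * c)


@dataclass
class NeTrajectory:
    bins: pd.DataFrame      # c, t_generations, mean_r2, n_pairs, ne
    n_correction: int       # the n of the 1/n finite-sample term

    def ne_at(self, t: float) -> float:
        i = (self.bins["t_generations"] - t).abs().idxmin()
        return float(self.bins.loc[i, "ne"])


def _pair_stats_by_chrom(gm: GenotypeMatrix, group: str, gmap: GeneticMap):
    """Per chromosome: (r2 matrix, genetic distance matrix, upper-tri index)."""
    idx = gm.group_index(group)
    chroms = gm.sites["chrom"].to_numpy()
    pos = gm.sites["pos"].to_numpy()
    out = {}
    for chrom in dict.fromkeys(chroms):
        sel = np.flatnonzero(chroms == chrom)
        if len(sel) < 2:
            continue
        calls = gm.calls[np.ix_(idx, sel)]
        r2 = pairwise_complete_r2(calls)
        morgans = np.asarray(gmap.bp_to_morgans(chrom, pos[sel]), dtype=float)
        d = np.abs(morgans[:, None] - morgans[None, :])
        iu = np.triu_indices(len(sel), k=1)
        # drop monomorphic pairs (zero variance reported as r2 = 0 by the
        # pairwise routine but genuinely undefined)
        var_ok = calls.std(axis=0) > 0
        keep = var_ok[iu[0]] & var_ok[iu[1]]
        out[chrom] = (r2[iu][keep], d[iu][keep])
    return out


def ne_trajectory(gm: GenotypeMatrix, gmap: GeneticMap | None = None,
                  group: str = "breed", t_range=(1, 20)) -> NeTrajectory:
    """LD-based effective-population-size trajectory.

    Within-chromosome SNP pairs are binned by genetic distance with bin edges
    c = 1/(2t) for integer t in ``t_range``; each bin inverts the Sved
    relation at its mean distance. Bins with mean r^2 <= 1/n or no pairs are
    flagged undefined (NaN), never fabricated.

    Because r^2 here is the squared correlation of unphased dosages, the
    finite-sample floor of r^2 between unlinked sites is ~1/N for N sampled
    individuals (not 1/(2N) as for haplotype r^2); the 1/n term therefore
    uses n = number of individuals.
    """
    if gmap is None:
        gmap = GeneticMap()
    n_chrom = int(gm.group_index(group).size)   # individuals; see docstring
    if n_chrom < 2:
        raise ValueError("need at least 4 sampled chromosomes (2 individuals)")
    stats = _pair_stats_by_chrom(gm, group, gmap)
    r2_all = np.concatenate([v[0] for v in stats.values()])
    d_all = np.concatenate([v[1] for v in stats.values()])
    t_lo, t_hi = t_range
    edges = np.array([1.0 / (2.0 * t) for t in range(t_lo, t_hi + 1)])  # descending
    rows = []
    for k in range(len(edges) - 1):
        hi, lo = edges[k], edges[k + 1]
        mask = (d_all >= lo) & (d_all < hi)
        n_pairs = int(mask.sum())
        if n_pairs == 0:
            rows.append({"c": 0.5 * (lo + hi), "t_generations": np.nan,
                         "mean_r2": np.nan, "n_pairs": 0, "ne": np.nan})
            continue
        cbar = float(d_all[mask].mean())
        r2bar = float(r2_all[mask].mean())
        rows.append({"c": cbar, "t_generations": 1.0 / (2.0 * cbar),
                     "mean_r2": r2bar, "n_pairs": n_pairs,
                     "ne": invert_sved(r2bar, cbar, n_chrom)})
    return NeTrajectory(bins=pd.DataFrame(rows), n_correction=n_chrom)


@dataclass
class AdmixtureDate:
    estimate: float                 # generations before sampling
    ci: tuple                       # (low, high)
    method: str                     # "weighted_ld" or "switches"
    generation_time_years: int = 3
    reference_year: int | None = None

    def to_years(self):
        if self.reference_year is None:
            raise ValueError("reference_year required for calendar conversion")
        return generations_to_years(self.estimate,
                                    (self.estimate - self.ci[0], self.ci[1] - self.estimate),
                                    self.generation_time_years, self.reference_year)


def _weighted_ld_components(gm: GenotypeMatrix, p_wolf, p_dog, gmap, group,
                            d_min, d_max, n_bins) -> dict:
    """Per-chromosome binned (sum of statistic, pair count, sum of d)."""
    idx = gm.group_index(group)
    chroms_all = gm.sites["chrom"].to_numpy()
    pos = gm.sites["pos"].to_numpy()
    w = p_wolf - p_dog
    edges = np.linspace(d_min, d_max, n_bins + 1)
    dos = gm.dosages()[idx]
    out = {}
    for chrom in dict.fromkeys(chroms_all):
        sel = np.flatnonzero(chroms_all == chrom)
        if len(sel) < 2:
            continue
        x = dos[:, sel]
        col_mean = np.nanmean(x, axis=0)
        x = np.where(np.isnan(x), col_mean, x) - col_mean
        cov = (x.T @ x) / max(len(idx) - 1, 1)
        stat = cov * np.outer(w[sel], w[sel])
        morgans = np.asarray(gmap.bp_to_morgans(chrom, pos[sel]), dtype=float)
        d = np.abs(morgans[:, None] - morgans[None, :])
        iu = np.triu_indices(len(sel), k=1)
        dv, sv = d[iu], stat[iu]
        which = np.digitize(dv, edges) - 1
        ok = (which >= 0) & (which < n_bins)
        num = np.zeros(n_bins)
        cnt = np.zeros(n_bins, dtype=np.int64)
        dsum = np.zeros(n_bins)
        np.add.at(num, which[ok], sv[ok])
        np.add.at(cnt, which[ok], 1)
        np.add.at(dsum, which[ok], dv[ok])
        out[chrom] = (num, cnt, dsum)
    return out


def _combine_components(components: dict, chromosomes) -> pd.DataFrame:
    num = sum(components[c][0] for c in chromosomes if c in components)
    cnt = sum(components[c][1] for c in chromosomes if c in components)
    dsum = sum(components[c][2] for c in chromosomes if c in components)
    with np.errstate(invalid="ignore", divide="ignore"):
        curve = pd.DataFrame({
            "d": np.where(cnt > 0, dsum / np.maximum(cnt, 1), np.nan),
            "weighted_ld": np.where(cnt > 0, num / np.maximum(cnt, 1), np.nan),
            "n_pairs": cnt,
        })
    return curve.dropna().reset_index(drop=True)


def weighted_ld_curve(gm: GenotypeMatrix, p_wolf: np.ndarray, p_dog: np.ndarray,
                      gmap: GeneticMap | None = None, group: str = "breed",
                      d_min: float = 0.002, d_max: float = 0.25,
                      n_bins: int = 30, chromosomes=None) -> pd.DataFrame:
    """Binned admixture-LD statistic vs genetic distance.

    Per pair (i, j) on one chromosome, the statistic is the sample covariance
    of breed dosages times the parental frequency contrasts
    (p_wolf - p_dog)_i (p_wolf - p_dog)_j, averaged within distance bins.
    """
    if gmap is None:
        gmap = GeneticMap()
    comp = _weighted_ld_components(gm, p_wolf, p_dog, gmap, group,
                                   d_min, d_max, n_bins)
    use = list(comp) if chromosomes is None else chromosomes
    return _combine_components(comp, use)


def fit_exponential_decay(d: np.ndarray, y: np.ndarray, g0: float = 10.0):
    """Fit y = a * exp(-g * d) + k; returns (a, g, k)."""
    d = np.asarray(d, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(d) < 4:
        raise ValueError("need at least 4 usable distance bins")
    k0 = float(np.mean(y[-max(len(y) // 5, 1):]))
    a0 = float(y[0] - k0)
    if a0 == 0:
        a0 = 1e-6
    popt, _ = curve_fit(lambda x, a, g, k: a * np.exp(-g * x) + k,
                        d, y, p0=[a0, g0, k0], maxfev=20000)
    return tuple(popt)


def admixture_ld_decay(gm: GenotypeMatrix, p_wolf: np.ndarray, p_dog: np.ndarray,
                       gmap: GeneticMap | None = None, group: str = "breed",
                       n_boot: int = 50, seed: int = 0,
                       amplitude_floor: float = 1e-8, **curve_kw) -> AdmixtureDate:
    """Date the admixture by the exponential decay rate of weighted LD.

    The decay rate g of a * exp(-g * d) + k estimates generations since
    admixture. The CI is a percentile bootstrap over chromosomes. A fitted
    amplitude below ``amplitude_floor`` means no admixture-LD signal; the
    date is then flagged unidentifiable (NaN estimate).
    """
    if gmap is None:
        gmap = GeneticMap()
    kw = {k_: curve_kw.get(k_, v) for k_, v in
          (("d_min", 0.002), ("d_max", 0.25), ("n_bins", 30))}
    comp = _weighted_ld_components(gm, p_wolf, p_dog, gmap, group, **kw)
    curve = _combine_components(comp, list(comp))
    a, g, k = fit_exponential_decay(curve["d"].to_numpy(), curve["weighted_ld"].to_numpy())
    if abs(a) < amplitude_floor:
        return AdmixtureDate(estimate=float("nan"), ci=(float("nan"), float("nan")),
                             method="weighted_ld")
    rng = np.random.default_rng(seed)
    chroms = list(comp)
    boots = []
    for _ in range(n_boot):
        pick = [chroms[t] for t in rng.integers(0, len(chroms), size=len(chroms))]
        try:
            cb = _combine_components(comp, pick)
            _ab, gb, _kb = fit_exponential_decay(cb["d"].to_numpy(),
                                                 cb["weighted_ld"].to_numpy(), g0=g)
            boots.append(gb)
        except (RuntimeError, ValueError):
            continue
    if len(boots) >= 10:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = g
    return AdmixtureDate(estimate=float(g), ci=(float(lo), float(hi)),
                         method="weighted_ld")


def switch_dating(s: float, q: float, genome_length_morgans: float) -> float:
    """Generations since admixture from the diploid ancestry-junction count.

    g = 1 + S / (4 L q (1 - q)); an F1 (S = 0) dates to one generation.
    """
    if not (0 < q < 1):
        raise ValueError("q must be strictly between 0 and 1")
    if genome_length_morgans <= 0:
        raise ValueError("genome length must be positive")
    if s < 0:
        raise ValueError("switch count must be non-negative")
    return 1.0 + s / (4.0 * genome_length_morgans * q * (1.0 - q))


def switch_dating_cohort(switches: pd.Series, q: pd.Series,
                         genome_length_morgans: float) -> pd.DataFrame:
    """Per-individual switch dating plus cohort summary row."""
    rows = []
    for sid in switches.index:
        rows.append({"sample": sid, "switches": float(switches[sid]),
                     "q": float(q[sid]),
                     "generations": switch_dating(switches[sid], q[sid],
                                                  genome_length_morgans)})
    df = pd.DataFrame(rows).set_index("sample")
    return df


def generations_to_years(g: float, ci=None, generation_time: int = 3,
                         reference_year: int | None = None) -> dict:
    """Convert generations before sampling into calendar years.

    ``ci`` may be a scalar half-width or a (minus, plus) pair of generation
    offsets. ``reference_year`` (the sampling year) is required.
    """
    if reference_year is None:
        raise ValueError("reference_year must be given explicitly")
    if ci is None:
        lo_g = hi_g = 0.0
    elif np.isscalar(ci):
        lo_g = hi_g = float(ci)
    else:
        lo_g, hi_g = float(ci[0]), float(ci[1])
    year = round(reference_year - g * generation_time)
    return {
        "year": int(year),
        "year_early": int(round(reference_year - (g + hi_g) * generation_time)),
        "year_late": int(round(reference_year - (g - lo_g) * generation_time)),
        "generations": float(g),
    }


def drift_accumulation(mu: float, n_generations: float, ne: float) -> float:
    """Expected new-variant fraction p = mu * generations * N_E."""
    if min(mu, n_generations, ne) < 0:
        raise ValueError("inputs must be non-negative")
    return mu * n_generations * ne


__all__ = [
    "sved_expected_r2", "invert_sved", "NeTrajectory", "ne_trajectory",
    "AdmixtureDate", "weighted_ld_curve", "fit_exponential_decay",
    "admixture_ld_decay", "switch_dating", "switch_dating_cohort",
    "generations_to_years", "drift_accumulation",
]
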