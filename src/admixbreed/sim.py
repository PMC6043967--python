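"""Forward-in-time, pedigree-recorded simulator of a wolf x dog hybrid breed.

Two parental gene pools are drawn under a Balding-Nichols divergence model
around a shared ancestral allele frequency, so the realized parental F_ST can
be dialled to the wolf/shepherd regime (~0.3-0.6). A breeding schedule then
founds an F1 generation (the 1958-style cross), backcrosses to the domestic
parent, injects single wild founders at scheduled generations (the four
registered wolf crossings), and closes the studbook, with a "popular sire"
concentration parameter weighting male contributions. Meioses are simulated
as Poisson crossovers on a genetic map with exact transmission of ancestry
segments, so the simulator returns genotypes, phased haplotypes, the full
pedigree, and ground-truth local ancestry for every sampled haplotype.

Founder haplotypes are drawn independently per site (no background LD): all
LD in the breed arises from admixture and drift, which is precisely the
signal the downstream dating methods exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, GeneticMap, GenotypeMatrix, HaplotypeSet
from .pedigree import Pedigree

WOLF, DOG = "wolf", "dog"

EVENT_KINDS = ("found_f1", "wolf_introgression", "dog_backcross", "closed_breeding")


@dataclass
class FounderModel:
    """Parental gene-pool model.

    ``divergence_fst`` is the Balding-Nichols divergence of each parental
    population from their shared ancestor; for two populations the expected
    pairwise F_ST between them equals this parameter.
    """

    n_sites: int = 2000                      # per chromosome
    chrom_lengths: dict = field(default_factory=lambda: {str(c): 50_000_000 for c in range(1, 6)})
    ancestral_beta: tuple = (0.8, 0.8)
    divergence_fst: float = 0.35
    # within-population inbreeding of sampled parental individuals (site-wise
    # autozygosity), in the regime reported for wolves and working dog breeds
    founder_inbreeding: dict = field(default_factory=lambda: {WOLF: 0.08, DOG: 0.16})
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.divergence_fst < 1):
            raise ValueError("divergence_fst must be in [0, 1)")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")

    def site_table(self) -> pd.DataFrame:
        chroms, pos = [], []
        for chrom, length in self.chrom_lengths.items():
            p = np.linspace(0, length, self.n_sites + 2, dtype=np.int64)[1:-1]
            p = np.unique(p)
            chroms += [chrom] * len(p)
            pos.append(p)
        return pd.DataFrame(
            {"chrom": np.array(chroms, dtype=object), "pos": np.concatenate(pos),
             "allele1": "A", "allele2": "B"}
        )


@dataclass
class BreedingEvent:
    generation: int
    kind: str
    census: int
    sire_concentration: float = 1.0
    outcross_fraction: float = 0.25   # fraction of offspring with the new outside parent

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.census < 2:
            raise ValueError("census must be >= 2")
        if self.sire_concentration <= 0:
            raise ValueError("sire concentration must be > 0")


@dataclass
class BreedingSchedule:
    """Ordered per-generation breeding plan.

    Generations not named by an event are closed breeding at the previous
    census. The first event must be ``found_f1`` at generation 0.
    """

    events: list
    generation_time_years: int = 3
    founding_year: int = 1958

    def __post_init__(self):
        if not self.events:
            raise ValueError("empty schedule")
        gens = [e.generation for e in self.events]
        if gens != sorted(gens) or len(set(gens)) != len(gens):
            raise ValueError("event generations must be strictly increasing")
        if self.events[0].generation != 0 or self.events[0].kind != "found_f1":
            raise ValueError("schedule must start with found_f1 at generation 0")

    @property
    def n_generations(self) -> int:
        return self.events[-1].generation

    def plan(self) -> list:
        """Expand to one event per generation 0..n_generations."""
        by_gen = {e.generation: e for e in self.events}
        out, census = [], self.events[0].census
        for g in range(self.n_generations + 1):
            if g in by_gen:
                out.append(by_gen[g])
                census = by_gen[g].census
            else:
                out.append(BreedingEvent(g, "closed_breeding", census))
        return out

    def sampling_year(self) -> int:
        return self.founding_year + self.n_generations * self.generation_time_years

    def last_admixture_generation(self) -> int:
        gens = [e.generation for e in self.events
                if e.kind in ("found_f1", "wolf_introgression", "dog_backcross")]
        return max(gens)

    def mean_admixture_age(self) -> float:
        """Outcross-fraction-weighted mean age of admixture events.

        Age of an event at generation g is (sampling generation - g + 1)
        generations before sampling; the founding cross has weight 1, later
        events their outcross fraction. This is the single-pulse age a
        weighted-LD decay fit is expected to recover when admixture arrived
        in several pulses.
        """
        sampling = self.n_generations + 1
        ages, weights = [], []
        for e in self.events:
            if e.kind == "found_f1":
                ages.append(sampling - e.generation)
                weights.append(1.0)
            elif e.kind in ("wolf_introgression", "dog_backcross"):
                ages.append(sampling - e.generation)
                weights.append(e.outcross_fraction)
        return float(np.average(ages, weights=weights))


def cwd_schedule(n_generations: int = 18, census_start: int = 40, census_end: int = 20,
                 sire_concentration: float = 1.0) -> BreedingSchedule:
    """Default schedule mirroring the Czechoslovakian Wolfdog history.

    F1 founded at generation 0 (1958); wolf introgressions at generations
    1, 3, 5 and 8 (~1960, 1968, 1974 and 1983 at 3 years/generation); heavy
    backcrossing to the domestic parent in between (generations 2, 4, 6, 7);
    closed breeding afterwards up to the sampling generation, with the census
    declining linearly. The resulting pedigree expectation of wolf ancestry
    at sampling is ~0.31, in the regime reported for the real breed.
    """
    census = np.linspace(census_start, census_end, n_generations + 1).round().astype(int)

    def ev(g, kind, f=0.25):
        return BreedingEvent(g, kind, int(census[g]), sire_concentration, f)

    events = [ev(0, "found_f1")]
    for g in range(1, n_generations + 1):
        if g in (1, 3, 5, 8):
            events.append(ev(g, "wolf_introgression", 0.2))
        elif g in (2, 4, 6, 7):
            events.append(ev(g, "dog_backcross", 0.5))
        elif g == n_generations:
            events.append(ev(g, "closed_breeding"))
    return BreedingSchedule(events=events)


def simulate_founder_freqs(model: FounderModel, rng=None):
    """Draw per-site (wolf, dog) allele frequencies under Balding-Nichols.

    Returns a pair of arrays over the concatenated site table. At
    ``divergence_fst = 0`` both populations equal the ancestral draw.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    n = model.n_sites * len(model.chrom_lengths)
    a, b = model.ancestral_beta
    p_anc = np.clip(rng.beta(a, b, size=n), 0.02, 0.98)
    fst = model.divergence_fst
    if fst == 0:
        return p_anc.copy(), p_anc.copy()
    c = (1.0 - fst) / fst
    p_wolf = rng.beta(np.maximum(c * p_anc, 1e-9), np.maximum(c * (1 - p_anc), 1e-9))
    p_dog = rng.beta(np.maximum(c * p_anc, 1e-9), np.maximum(c * (1 - p_anc), 1e-9))
    return p_wolf, p_dog


# ---------------------------------------------------------------------------
# internal haplotype representation: per chromosome, (breakpoints, founder ids)
# breakpoints[0] = 0, breakpoints[-1] = chrom length; founder ids index the
# founder-haplotype registry.


class _Individual:
    __slots__ = ("id", "sex", "sire", "dam", "generation", "haps")

    def __init__(self, id, sex, sire, dam, generation, haps):
        self.id = id
        self.sex = sex
        self.sire = sire
        self.dam = dam
        self.generation = generation
        self.haps = haps  # [hap0, hap1]; hap = {chrom: (bnds, ids)}


@dataclass
class SimulationResult:
    genotypes: GenotypeMatrix
    haplotypes: HaplotypeSet
    pedigree: Pedigree
    truth_tracks: dict          # hap id -> list of (chrom, start, end, origin)
    truth_q: dict               # breed sample id -> wolf fraction of genome
    founder_freqs: tuple        # (p_wolf, p_dog) arrays over sites
    model: FounderModel
    schedule: BreedingSchedule
    seed: int

    def breed_sample_ids(self) -> list:
        return [s for s, g in zip(self.genotypes.sample_ids, self.genotypes.groups)
                if g == "breed"]

    def origin_at(self, hap_id: str, chrom, bp: float) -> str:
        """Ground-truth ancestry of one haplotype at a genomic position."""
        for c, s, e, origin in self.truth_tracks[hap_id]:
            if c == chrom and s <= bp < e:
                return origin
        raise KeyError(f"position {chrom}:{bp} not covered for {hap_id}")

    def true_switches(self, sample_id) -> int:
        """Ground-truth ancestry junction count over both haplotypes."""
        n = 0
        for k in (1, 2):
            segs = self.truth_tracks[f"{sample_id}_h{k}"]
            by_chrom: dict = {}
            for chrom, _s, _e, origin in segs:
                by_chrom.setdefault(chrom, []).append(origin)
            for origins in by_chrom.values():
                n += sum(1 for a, b in zip(origins, origins[1:]) if a != b)
        return n


def _whole_chrom_hap(chrom_lengths, founder_hap_id):
    return {chrom: (np.array([0, length], dtype=np.int64),
                    np.array([founder_hap_id], dtype=np.int64))
            for chrom, length in chrom_lengths.items()}


def _meiosis(ind: _Individual, chrom_lengths, gmap: GeneticMap, rng):
    """One gamete: Poisson crossovers on the genetic map, no interference."""
    gamete = {}
    for chrom, length in chrom_lengths.items():
        morgans = gmap.chrom_length_morgans(chrom, length)
        n_x = rng.poisson(morgans)
        # linear map: uniform in genetic distance == uniform in bp
        xs = np.sort(rng.integers(1, length, size=n_x)) if n_x else np.empty(0, dtype=np.int64)
        xs = np.unique(xs)
        start = rng.integers(0, 2)
        cuts = np.concatenate(([0], xs, [length]))
        bnds_out, ids_out = [0], []
        for k in range(len(cuts) - 1):
            lo, hi = int(cuts[k]), int(cuts[k + 1])
            if lo == hi:
                continue
            src_bnds, src_ids = ind.haps[(start + k) % 2][chrom]
            i0 = np.searchsorted(src_bnds, lo, side="right") - 1
            i1 = np.searchsorted(src_bnds, hi, side="left")
            for seg in range(i0, i1):
                s = max(lo, int(src_bnds[seg]))
                e = min(hi, int(src_bnds[seg + 1]))
                if s >= e:
                    continue
                fid = int(src_ids[seg])
                if ids_out and ids_out[-1] == fid:
                    bnds_out[-1] = e
                else:
                    bnds_out.append(e)
                    ids_out.append(fid)
        gamete[chrom] = (np.array(bnds_out, dtype=np.int64), np.array(ids_out, dtype=np.int64))
    return gamete


class _FounderRegistry:
    """Founder haplotype alleles and population of origin."""

    def __init__(self, p_wolf, p_dog, rng, inbreeding=None):
        self.p = {WOLF: p_wolf, DOG: p_dog}
        self.f = inbreeding or {}
        self.rng = rng
        self.alleles: list = []   # each entry: int8 array over all sites
        self.origin: list = []    # WOLF or DOG per haplotype

    def new_founder_haps(self, pop: str) -> tuple[int, int]:
        p = self.p[pop]
        h1 = (self.rng.random(len(p)) < p).astype(np.int8)
        h2 = (self.rng.random(len(p)) < p).astype(np.int8)
        f = self.f.get(pop, 0.0)
        if f > 0:
            # site-wise autozygosity: with probability f the two alleles of
            # this individual are identical by descent
            ibd = self.rng.random(len(p)) < f
            h2[ibd] = h1[ibd]
        self.alleles += [h1, h2]
        self.origin += [pop, pop]
        return len(self.alleles) - 2, len(self.alleles) - 1


def _assign_sexes(rng, n):
    sexes = np.where(rng.random(n) < 0.5, "M", "F")
    if (sexes == "M").all():
        sexes[0] = "F"
    if (sexes == "F").all():
        sexes[0] = "M"
    return sexes


def simulate_breed(model: FounderModel, schedule: BreedingSchedule,
                   gmap: GeneticMap | None = None, seed: int = 0,
                   n_founder_wolves: int = 2, n_founder_dogs: int = 4,
                   n_ref_wolf: int = 12, n_ref_dog: int = 12,
                   sample_generations=None) -> SimulationResult:
    """Run the breeding schedule and return genotypes, haplotypes and truth.

    Sampled individuals are the parental reference panels (``n_ref_wolf`` /
    ``n_ref_dog`` individuals drawn from the founder gene pools, groups
    ``wild_parent`` / ``dom_parent``) plus every breed individual of the
    sampling generation(s) (default: the last generation), group ``breed``.
    """
    if gmap is None:
        gmap = GeneticMap()
    rng = np.random.default_rng(seed)
    sites = model.site_table()
    p_wolf, p_dog = simulate_founder_freqs(model, rng)
    registry = _FounderRegistry(p_wolf, p_dog, rng, model.founder_inbreeding)
    ped = Pedigree()
    chrom_lengths = model.chrom_lengths

    def make_founder(pop, name, sex, generation):
        h0, h1 = registry.new_founder_haps(pop)
        ind = _Individual(name, sex, None, None, generation,
                          [_whole_chrom_hap(chrom_lengths, h0),
                           _whole_chrom_hap(chrom_lengths, h1)])
        ped.add(name, pop_label=pop, generation=generation)
        return ind

    def breed_offspring(name, sire, dam, generation):
        haps = [_meiosis(sire, chrom_lengths, gmap, rng),
                _meiosis(dam, chrom_lengths, gmap, rng)]
        ind = _Individual(name, None, sire.id, dam.id, generation, haps)
        ped.add(name, sire=sire.id, dam=dam.id, generation=generation)
        return ind

    plan = schedule.plan()
    generations: dict[int, list] = {}
    founder_count = {WOLF: 0, DOG: 0}

    def next_founder(pop, generation, sex):
        founder_count[pop] += 1
        tag = "W" if pop == WOLF else "D"
        return make_founder(pop, f"{tag}{founder_count[pop]:03d}", sex, generation)

    for ev in plan:
        g = ev.generation
        offspring = []
        if ev.kind == "found_f1":
            wolves = [next_founder(WOLF, g, "F") for _ in range(n_founder_wolves)]
            dogs = [next_founder(DOG, g, "M") for _ in range(n_founder_dogs)]
            for k in range(ev.census):
                sire = dogs[rng.integers(len(dogs))]
                dam = wolves[rng.integers(len(wolves))]
                offspring.append(breed_offspring(f"G{g:02d}_I{k:03d}", sire, dam, g + 1))
        else:
            pool = generations[g]  # individuals born into generation g
            males = [i for i in pool if i.sex == "M"]
            females = [i for i in pool if i.sex == "F"]
            if not males or not females:
                raise RuntimeError(f"census collapse at generation {g}: no breeding pairs")
            sire_w = rng.dirichlet([ev.sire_concentration] * len(males))
            outsiders = []
            if ev.kind in ("wolf_introgression", "dog_backcross"):
                pop = WOLF if ev.kind == "wolf_introgression" else DOG
                n_out = int(round(ev.outcross_fraction * ev.census))
                # a single registered wolf per introgression; backcrossing to
                # the domestic breed draws a fresh sire/dam per litter-sized
                # batch of ~5 offspring
                n_founders = 1 if pop == WOLF else max(1, int(np.ceil(n_out / 5)))
                for _ in range(n_founders):
                    sex = "M" if rng.random() < 0.5 else "F"
                    outsiders.append(next_founder(pop, g, sex))
            else:
                n_out = 0
            for k in range(ev.census):
                if k < n_out:
                    outsider = outsiders[k % len(outsiders)]
                    if outsider.sex == "M":
                        sire = outsider
                        dam = females[rng.integers(len(females))]
                    else:
                        sire = males[rng.choice(len(males), p=sire_w)]
                        dam = outsider
                else:
                    sire = males[rng.choice(len(males), p=sire_w)]
                    dam = females[rng.integers(len(females))]
                offspring.append(breed_offspring(f"G{g:02d}_I{k:03d}", sire, dam, g + 1))
        sexes = _assign_sexes(rng, len(offspring))
        for ind, s in zip(offspring, sexes):
            ind.sex = s
        generations[g + 1] = offspring

    # ---- sampling ---------------------------------------------------------
    last_gen = schedule.n_generations + 1
    if sample_generations is None:
        sample_generations = [last_gen]
    breed_samples = [ind for g in sample_generations for ind in generations[g]]

    site_chrom = sites["chrom"].to_numpy()
    site_pos = sites["pos"].to_numpy()
    chrom_slices = {}
    for chrom in chrom_lengths:
        idx = np.flatnonzero(site_chrom == chrom)
        chrom_slices[chrom] = (idx[0], idx[-1] + 1)

    def hap_alleles(hap) -> np.ndarray:
        out = np.empty(len(site_pos), dtype=np.int8)
        for chrom, (lo, hi) in chrom_slices.items():
            bnds, ids = hap[chrom]
            pos = site_pos[lo:hi]
            seg = np.searchsorted(bnds, pos, side="right") - 1
            seg = np.clip(seg, 0, len(ids) - 1)
            for s in np.unique(seg):
                mask = seg == s
                out[lo:hi][mask] = registry.alleles[ids[s]][lo:hi][mask]
        return out

    sample_ids, groups, hap_rows = [], [], []
    truth_tracks, truth_q = {}, {}

    for j in range(n_ref_wolf):
        name = f"WREF{j:02d}"
        h0, h1 = registry.new_founder_haps(WOLF)
        sample_ids.append(name)
        groups.append("wild_parent")
        hap_rows += [registry.alleles[h0], registry.alleles[h1]]
    for j in range(n_ref_dog):
        name = f"DREF{j:02d}"
        h0, h1 = registry.new_founder_haps(DOG)
        sample_ids.append(name)
        groups.append("dom_parent")
        hap_rows += [registry.alleles[h0], registry.alleles[h1]]

    total_len = float(sum(chrom_lengths.values()))
    for ind in breed_samples:
        sample_ids.append(ind.id)
        groups.append("breed")
        wolf_len = 0.0
        for k, hap in enumerate(ind.haps):
            hap_rows.append(hap_alleles(hap))
            segs = []
            for chrom in chrom_lengths:
                bnds, ids = hap[chrom]
                for s in range(len(ids)):
                    origin = registry.origin[ids[s]]
                    start, end = int(bnds[s]), int(bnds[s + 1])
                    if segs and segs[-1][0] == chrom and segs[-1][3] == origin and segs[-1][2] == start:
                        segs[-1] = (chrom, segs[-1][1], end, origin)
                    else:
                        segs.append((chrom, start, end, origin))
            truth_tracks[f"{ind.id}_h{k + 1}"] = segs
            wolf_len += sum(e - s for _c, s, e, o in segs if o == WOLF)
        truth_q[ind.id] = wolf_len / (2.0 * total_len)

    haplotypes = HaplotypeSet(sample_ids=sample_ids, sites=sites,
                              haplotypes=np.array(hap_rows, dtype=np.int8))
    genotypes = haplotypes.to_genotypes(groups=np.array(groups, dtype=object))

    return SimulationResult(
        genotypes=genotypes, haplotypes=haplotypes, pedigree=ped,
        truth_tracks=truth_tracks, truth_q=truth_q,
        founder_freqs=(p_wolf, p_dog), model=model, schedule=schedule, seed=seed,
    )


def inject_missingness(gm: GenotypeMatrix, rate: float, seed: int = 0) -> GenotypeMatrix:
    """Set each call missing independently with probability ``rate``."""
    if not (0 <= rate < 1):
        raise ValueError("rate must be in [0, 1)")
    if rate == 0:
        return gm
    rng = np.random.default_rng(seed)
    calls = gm.calls.copy()
    calls[rng.random(calls.shape) < rate] = MISSING
    return GenotypeMatrix(sample_ids=list(gm.sample_ids), groups=gm.groups.copy(),
                          sites=gm.sites.copy(), calls=calls)


__all__ = [
    "WOLF", "DOG", "FounderModel", "BreedingEvent", "BreedingSchedule",
    "SimulationResult", "cwd_schedule", "simulate_founder_freqs",
    "simulate_breed", "inject_missingness",
]
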