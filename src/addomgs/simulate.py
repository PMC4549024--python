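"""Forward simulation of a composite breeding population with LD.

Two random-mating founder populations in linkage equilibrium are crossed;
the cross is advanced by random mating (no mutation, selection or migration)
and a genotyped cohort of full-sib families is drawn from a limited parent
pool, producing a small effective population size and strong linkage
disequilibrium, as in elite plant breeding populations.

The module also provides the closed-form design calculators: the expected
composite-population LD, and the proportion of genetic variance captured by
the marker panel under three classical approximations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomeMap",
    "FounderSpec",
    "Population",
    "Cohort",
    "TraitArchitecture",
    "SimDataset",
    "expected_composite_ld",
    "marker_capture_ratio",
    "marker_capture_from_spacing",
    "haldane",
    "sample_gametes",
    "simulate_composite",
    "make_families",
    "assign_trait",
    "simulate_phenotypes",
    "enforce_maf",
    "estimate_ld",
    "simulate_dataset",
]


# ---------------------------------------------------------------------------
# Design calculators (closed form)
# ---------------------------------------------------------------------------

def expected_composite_ld(theta, pa1, pa2, pb1, pb2):
    """Expected LD (Delta) between two loci in a composite population.

    ``Delta_ab = ((1 - 2*theta)/4) * (pa1 - pa2) * (pb1 - pb2)`` where
    ``theta`` is the recombination fraction between the loci and ``p^1, p^2``
    are the allele frequencies in the two parental populations.  Positive for
    coupling, negative for repulsion; |Delta| is maximised at 0.25 when
    theta = 0 and the parental frequency difference is 1 at both loci.
    """
    theta = np.asarray(theta, dtype=float)
    freqs = [np.asarray(p, dtype=float) for p in (pa1, pa2, pb1, pb2)]
    if np.any(theta < 0) or np.any(theta > 0.5):
        raise ValueError("recombination fraction theta must lie in [0, 0.5]")
    for p in freqs:
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("allele frequencies must lie in [0, 1]")
    pa1, pa2, pb1, pb2 = freqs
    out = (1.0 - 2.0 * theta) / 4.0 * (pa1 - pa2) * (pb1 - pb2)
    return out if out.ndim else float(out)


def marker_capture_ratio(n, n_qtl):
    """Proportion of genetic variance captured by markers, n / (n + n_QTL).

    ``n_qtl`` may be the literal QTL count or the effective number of
    chromosome segments 2*Ne*L.
    """
    if n <= 0:
        raise ValueError("marker count n must be positive")
    if n_qtl < 0:
        raise ValueError("n_qtl must be non-negative")
    return n / (n + n_qtl)


def marker_capture_from_spacing(ne, spacing_morgans):
    """Marker-capture proportion from marker spacing: 1 / (1 + 4*Ne*S)."""
    if ne <= 0:
        raise ValueError("effective size Ne must be positive")
    if spacing_morgans < 0:
        raise ValueError("marker spacing must be non-negative")
    return 1.0 / (1.0 + 4.0 * ne * spacing_morgans)


def haldane(d_morgans):
    """Haldane map function: recombination fraction for a map distance."""
    d = np.asarray(d_morgans, dtype=float)
    c = 0.5 * (1.0 - np.exp(-2.0 * d))
    return c if c.ndim else float(c)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeMap:
    """Chromosome layout with equidistant markers.

    Defaults follow the study design: 10 chromosomes x 20 cM, markers every
    0.1 cM (2,000 loci, L = 2 Morgans, spacing S = 0.001 Morgans), 100 of the
    loci designated as QTL.
    """

    positions_cm: np.ndarray          # cM position within chromosome, per locus
    chrom: np.ndarray                 # chromosome index per locus
    qtl_indices: np.ndarray           # locus indices that are QTL

    def __post_init__(self):
        self.positions_cm = np.asarray(self.positions_cm, dtype=float)
        self.chrom = np.asarray(self.chrom, dtype=np.int32)
        self.qtl_indices = np.asarray(self.qtl_indices, dtype=np.int64)
        if self.positions_cm.size == 0:
            raise ValueError("genome map must contain at least one locus")
        if self.positions_cm.shape != self.chrom.shape:
            raise ValueError("positions and chromosome labels must align")
        if self.qtl_indices.size and (
            self.qtl_indices.min() < 0 or self.qtl_indices.max() >= self.n_loci
        ):
            raise ValueError("qtl_indices out of range")

    @property
    def n_loci(self) -> int:
        return self.positions_cm.size

    @property
    def n_chromosomes(self) -> int:
        return int(np.unique(self.chrom).size)

    @property
    def total_length_morgans(self) -> float:
        L = 0.0
        for c in np.unique(self.chrom):
            pos = self.positions_cm[self.chrom == c]
            L += (pos.max() - pos.min()) / 100.0
        return L

    @property
    def marker_spacing_morgans(self) -> float:
        """Median spacing between adjacent markers, in Morgans."""
        gaps = []
        for c in np.unique(self.chrom):
            pos = np.sort(self.positions_cm[self.chrom == c])
            if pos.size > 1:
                gaps.append(np.diff(pos))
        if not gaps:
            return 0.0
        return float(np.median(np.concatenate(gaps))) / 100.0

    def switch_probs(self) -> np.ndarray:
        """Per-locus haplotype-switch probabilities for gamete sampling.

        Entry j is the probability that the parental strand changes between
        locus j-1 and locus j: 0.5 at each chromosome start (independent
        assortment), Haldane c of the inter-marker distance elsewhere.
        """
        c = np.empty(self.n_loci)
        d_cm = np.diff(self.positions_cm, prepend=self.positions_cm[0])
        c[:] = haldane(np.maximum(d_cm, 0.0) / 100.0)
        starts = np.r_[True, self.chrom[1:] != self.chrom[:-1]]
        c[starts] = 0.5
        return c

    @classmethod
    def default(
        cls,
        n_chromosomes: int = 10,
        chrom_length_cm: float = 20.0,
        spacing_cm: float = 0.1,
        n_qtl: int = 100,
        seed: int | None = None,
    ) -> "GenomeMap":
        per_chrom = int(round(chrom_length_cm / spacing_cm))
        pos = np.tile(np.arange(per_chrom) * spacing_cm, n_chromosomes)
        chrom = np.repeat(np.arange(n_chromosomes), per_chrom)
        n_loci = pos.size
        if n_qtl > n_loci:
            raise ValueError("more QTL than loci")
        if seed is None:
            # deterministic even spread through the genome
            qtl = np.linspace(0, n_loci - 1, n_qtl, dtype=np.int64) if n_qtl else np.empty(0, np.int64)
        else:
            rng = np.random.default_rng(seed)
            qtl = np.sort(rng.choice(n_loci, size=n_qtl, replace=False))
        return cls(pos, chrom, qtl)


@dataclass
class FounderSpec:
    """Allele frequencies of the two crossed founder populations.

    Both founder populations are in linkage equilibrium; the LD of the
    composite arises purely from their frequency divergence.  The default
    scheme draws p1 ~ U(0.05, 0.95) and sets p2 = 1 - p1 (maximal
    divergence), reproducing the strong-LD regime; a "mild" scheme draws the
    two frequency vectors independently.
    """

    p1: np.ndarray
    p2: np.ndarray
    scheme: str = "maximal"
    ne_target: float = 39.22

    def __post_init__(self):
        self.p1 = np.asarray(self.p1, dtype=float)
        self.p2 = np.asarray(self.p2, dtype=float)
        if self.p1.shape != self.p2.shape:
            raise ValueError("p1 and p2 must align")
        for p in (self.p1, self.p2):
            if np.any(p <= 0) or np.any(p >= 1):
                raise ValueError("founder frequencies must lie strictly in (0, 1)")

    @classmethod
    def draw(
        cls,
        gmap: GenomeMap,
        rng: np.random.Generator,
        low: float = 0.05,
        high: float = 0.95,
        scheme: str = "maximal",
        ne_target: float = 39.22,
    ) -> "FounderSpec":
        p1 = rng.uniform(low, high, size=gmap.n_loci)
        if scheme == "maximal":
            p2 = 1.0 - p1
        elif scheme == "mild":
            p2 = rng.uniform(low, high, size=gmap.n_loci)
        else:
            raise ValueError(f"unknown divergence scheme {scheme!r}")
        return cls(p1, p2, scheme=scheme, ne_target=ne_target)


@dataclass
class Population:
    """Phased diploid population: haplotypes with shape (n, 2, n_loci)."""

    haplotypes: np.ndarray
    generation: int = 0

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n, 2, n_loci)")

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[2]

    def dosages(self) -> np.ndarray:
        """Genotype dosages 0/1/2 (count of the '1' allele)."""
        return self.haplotypes.sum(axis=1, dtype=np.uint8)

    def allele_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=(0, 1))


@dataclass
class Cohort(Population):
    """Genotyped/phenotyped cohort of full-sib families with its pedigree.

    ``sire``/``dam`` index into the parent pool (the cohort's founders);
    founders themselves are unrelated non-inbred members of the composite.
    """

    family_id: np.ndarray = field(default_factory=lambda: np.empty(0, np.int32))
    sire: np.ndarray = field(default_factory=lambda: np.empty(0, np.int32))
    dam: np.ndarray = field(default_factory=lambda: np.empty(0, np.int32))
    n_founders: int = 0

    @property
    def n_families(self) -> int:
        return int(np.unique(self.family_id).size)

    def pedigree(self) -> tuple[np.ndarray, np.ndarray]:
        """Full pedigree arrays (sire, dam) with founders first, -1 = unknown."""
        nf = self.n_founders
        sire = np.r_[np.full(nf, -1, np.int32), self.sire.astype(np.int32)]
        dam = np.r_[np.full(nf, -1, np.int32), self.dam.astype(np.int32)]
        return sire, dam

    @property
    def effective_size(self) -> float:
        """Inbreeding-effective size of the family-generation step,
        4*Nm*Nf/(Nm+Nf) over the distinct sires and dams actually used."""
        nm = np.unique(self.sire).size
        nf = np.unique(self.dam).size
        return 4.0 * nm * nf / (nm + nf)


# ---------------------------------------------------------------------------
# Meiosis and mating
# ---------------------------------------------------------------------------

def sample_gametes(
    parent_haps: np.ndarray, gmap: GenomeMap, rng: np.random.Generator
) -> np.ndarray:
    """One recombinant gamete per parental genotype in ``parent_haps``.

    ``parent_haps`` has shape (k, 2, n_loci); the returned array has shape
    (k, n_loci).  Recombination is modelled as a two-state Markov chain along
    each chromosome (strand switches between adjacent loci with the Haldane
    recombination fraction of their distance, independent starts per
    chromosome) — the no-interference model implied by the Haldane map.
    """
    parent_haps = np.asarray(parent_haps)
    k, two, n_loci = parent_haps.shape
    if n_loci != gmap.n_loci:
        raise ValueError("parent haplotypes do not match the genome map")
    c = gmap.switch_probs()
    switches = rng.random((k, n_loci)) < c
    # first column of `switches` has p=0.5 (chromosome start): random phase
    strand = np.cumsum(switches, axis=1, dtype=np.int32) & 1
    return np.take_along_axis(
        parent_haps, strand[:, None, :], axis=1
    )[:, 0, :].astype(np.uint8)


def sample_gamete(parent_haps: np.ndarray, gmap: GenomeMap, seed=None) -> np.ndarray:
    """Single-meiosis convenience wrapper around :func:`sample_gametes`."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return sample_gametes(np.asarray(parent_haps)[None, ...], gmap, rng)[0]


def simulate_composite(
    founders: FounderSpec,
    gmap: GenomeMap,
    n_generations: int = 5,
    pop_size: int = 5000,
    seed=None,
    breeding_size: int | None = None,
) -> Population:
    """Cross the two founder populations and advance by random mating.

    Generation 0 (the cross) receives one gamete drawn from each founder
    population (linkage equilibrium within each) and has ``pop_size``
    members; the subsequent random-mating generations are kept at
    ``breeding_size`` (default: ``pop_size``) — a small breeding size
    realises the small effective population size, and hence the drift
    component of LD, typical of elite breeding populations.  Each offspring
    is the union of recombinant gametes from two distinct random parents;
    no mutation, selection or migration.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    if pop_size < 2:
        raise ValueError("pop_size must be > 1")
    if gmap.n_loci != founders.p1.size:
        raise ValueError("founder frequencies do not match the genome map")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if breeding_size is None:
        breeding_size = pop_size
    if breeding_size < 2:
        raise ValueError("breeding_size must be > 1")

    n_loci = gmap.n_loci
    haps = np.empty((pop_size, 2, n_loci), dtype=np.uint8)
    haps[:, 0, :] = rng.random((pop_size, n_loci)) < founders.p1
    haps[:, 1, :] = rng.random((pop_size, n_loci)) < founders.p2
    pop = Population(haps, generation=0)

    for gen in range(1, n_generations + 1):
        sires = rng.integers(0, pop.n, size=breeding_size)
        dams = (sires + 1 + rng.integers(0, pop.n - 1, size=breeding_size)) % pop.n
        new = np.empty((breeding_size, 2, n_loci), dtype=np.uint8)
        new[:, 0, :] = sample_gametes(pop.haplotypes[sires], gmap, rng)
        new[:, 1, :] = sample_gametes(pop.haplotypes[dams], gmap, rng)
        pop = Population(new, generation=gen)
    return pop


def make_families(
    composite: Population,
    gmap: GenomeMap,
    n_families: int = 20,
    family_size: int = 50,
    n_parents: int = 40,
    seed=None,
) -> Cohort:
    """Draw the genotyped cohort: full-sib families from a limited parent pool.

    ``n_parents`` individuals are sampled from the composite; families pair
    distinct parents (monogamous when the pool is exactly 2*n_families).  The
    limited pool is what produces the small effective size of the breeding
    population; Ne is reported by :attr:`Cohort.effective_size`, not enforced.
    """
    if 2 * n_families > n_parents:
        raise ValueError("need at least two parents per family in the pool")
    if n_parents > composite.n:
        raise ValueError("parent pool larger than the composite population")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    pool = rng.choice(composite.n, size=n_parents, replace=False)
    order = rng.permutation(n_parents)
    sire_of_family = order[:n_families]
    dam_of_family = order[n_families : 2 * n_families]

    n_off = n_families * family_size
    family_id = np.repeat(np.arange(n_families, dtype=np.int32), family_size)
    sire = sire_of_family[family_id].astype(np.int32)
    dam = dam_of_family[family_id].astype(np.int32)

    parent_haps = composite.haplotypes[pool]
    haps = np.empty((n_off, 2, composite.n_loci), dtype=np.uint8)
    haps[:, 0, :] = sample_gametes(parent_haps[sire], gmap, rng)
    haps[:, 1, :] = sample_gametes(parent_haps[dam], gmap, rng)

    return Cohort(
        haplotypes=haps,
        generation=composite.generation + 1,
        family_id=family_id,
        sire=sire,
        dam=dam,
        n_founders=n_parents,
    )


# ---------------------------------------------------------------------------
# Trait architecture and phenotypes
# ---------------------------------------------------------------------------

@dataclass
class TraitArchitecture:
    """Per-QTL genotypic-value parameters of a simulated trait.

    At each QTL the three genotypes take values m + a (MM), m + d (Mm) and
    m - a (mm).  ``a`` and ``d`` are drawn from the same zero-mean normal
    (independent), giving a mean degree of dominance |d|/|a| near 1; for the
    major-gene architecture five QTL are rescaled to carry half the genetic
    variance.  ``sigma_e2`` is the residual variance that realises the target
    broad-sense heritability on the calibration cohort.
    """

    architecture: str
    qtl_indices: np.ndarray
    a: np.ndarray
    d: np.ndarray
    mean_m: float
    sigma_e2: float
    h2_broad: float
    h2_narrow: float
    major_indices: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    @property
    def gmax(self) -> float:
        """Genotypic value of the best complete homozygote, n_qtl*m + sum|a|."""
        return float(self.qtl_indices.size * self.mean_m + np.abs(self.a).sum())

    @property
    def gmin(self) -> float:
        return float(self.qtl_indices.size * self.mean_m - np.abs(self.a).sum())

    @property
    def degree_of_dominance(self) -> float:
        """Mean |d| relative to mean |a| across QTL (~1 = complete dominance)."""
        return float(np.abs(self.d).mean() / np.abs(self.a).mean())

    def genotypic_values(self, dosages: np.ndarray) -> np.ndarray:
        """Total genotypic value g for each individual (dosage-coded QTL)."""
        x = np.asarray(dosages)[:, self.qtl_indices].astype(float)
        add = (x - 1.0) @ self.a          # MM:+a, Mm:0, mm:-a
        dom = (x == 1.0) @ self.d
        return self.qtl_indices.size * self.mean_m + add + dom

    def true_components(self, dosages: np.ndarray):
        """True breeding values and dominance deviations in a cohort.

        Uses the cohort allele frequencies: u_a = W_qtl @ alpha with
        alpha_i = a_i + (q_i - p_i) d_i, and u_d = S_qtl @ d.
        """
        from .coding import code_additive, code_dominance  # local import: no cycle at module load

        x = np.asarray(dosages)[:, self.qtl_indices]
        p = x.mean(axis=0) / 2.0
        p = np.clip(p, 1e-6, 1 - 1e-6)
        alpha = self.a + (1.0 - 2.0 * p) * self.d
        u_a = code_additive(x, p) @ alpha
        u_d = code_dominance(x, p) @ self.d
        return u_a, u_d


def _variance_ratio(dosages_qtl, a, d):
    """Realized (Va, Vd) in a cohort for given per-QTL effects."""
    from .coding import code_additive, code_dominance

    p = dosages_qtl.mean(axis=0) / 2.0
    p = np.clip(p, 1e-6, 1 - 1e-6)
    alpha = a + (1.0 - 2.0 * p) * d
    u_a = code_additive(dosages_qtl, p) @ alpha
    u_d = code_dominance(dosages_qtl, p) @ d
    return float(np.var(u_a)), float(np.var(u_d))


def assign_trait(
    pop: Population,
    gmap: GenomeMap,
    architecture: str = "infinitesimal",
    h2_broad: float = 0.30,
    h2_narrow: float = 0.20,
    dominance_direction: str = "mixed",
    positive_fraction: float = 0.7,
    mean_m: float = 1.0,
    n_major: int = 5,
    major_share: float = 0.5,
    seed=None,
) -> TraitArchitecture:
    """Draw and calibrate QTL effects against the realized cohort.

    Additive and dominance effects are i.i.d. N(0, 1) draws; dominance signs
    follow ``dominance_direction`` ("mixed" flips 1 - positive_fraction of
    them negative, "positive" keeps all positive).  The dominance effects are
    then globally rescaled (iteratively, since the substitution effects alpha
    depend on d) so the realized Vd/Va in the cohort matches the target ratio
    (h2_broad - h2_narrow)/h2_narrow, and sigma_e2 is set so the realized
    broad-sense heritability equals ``h2_broad`` exactly on this cohort.
    """
    if not (0.0 < h2_narrow < h2_broad < 1.0):
        raise ValueError("need 0 < h2_narrow < h2_broad < 1")
    if architecture not in ("infinitesimal", "major_genes"):
        raise ValueError(f"unknown architecture {architecture!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    qtl = gmap.qtl_indices
    n_qtl = qtl.size
    dosages_qtl = pop.dosages()[:, qtl].astype(float)

    a = rng.standard_normal(n_qtl)
    d = rng.standard_normal(n_qtl)
    if dominance_direction == "positive":
        d = np.abs(d)
    elif dominance_direction == "mixed":
        sign = np.where(rng.random(n_qtl) < positive_fraction, 1.0, -1.0)
        d = np.abs(d) * sign
    else:
        raise ValueError(f"unknown dominance_direction {dominance_direction!r}")

    major = np.empty(0, dtype=np.int64)
    if architecture == "major_genes":
        major = np.sort(rng.choice(n_qtl, size=n_major, replace=False))

    # iterate: (i) major-gene variance share, (ii) dominance/additive ratio
    target_ratio = (h2_broad - h2_narrow) / h2_narrow
    for _ in range(20):
        if architecture == "major_genes":
            va, vd = _variance_ratio(dosages_qtl, a, d)
            mask = np.zeros(n_qtl, bool)
            mask[major] = True
            a_maj, d_maj = np.where(mask, a, 0.0), np.where(mask, d, 0.0)
            va_m, vd_m = _variance_ratio(dosages_qtl, a_maj, d_maj)
            share = (va_m + vd_m) / (va + vd)
            f = np.sqrt(major_share / (1.0 - major_share) * (va + vd - va_m - vd_m)
                        / max(va_m + vd_m, 1e-300))
            a[major] *= f
            d[major] *= f
        va, vd = _variance_ratio(dosages_qtl, a, d)
        ratio = vd / va
        t = np.sqrt(target_ratio / ratio)
        d *= t
        if abs(t - 1.0) < 1e-6 and (
            architecture != "major_genes" or abs(share - major_share) < 1e-4
        ):
            break

    va, vd = _variance_ratio(dosages_qtl, a, d)
    vg = float(np.var(TraitArchitecture(
        architecture, qtl, a, d, mean_m, 0.0, h2_broad, h2_narrow, major
    ).genotypic_values(pop.dosages())))
    sigma_e2 = vg * (1.0 - h2_broad) / h2_broad

    return TraitArchitecture(
        architecture=architecture,
        qtl_indices=qtl,
        a=a,
        d=d,
        mean_m=mean_m,
        sigma_e2=sigma_e2,
        h2_broad=h2_broad,
        h2_narrow=h2_narrow,
        major_indices=major,
    )


def simulate_phenotypes(pop: Population, trait: TraitArchitecture, seed=None) -> np.ndarray:
    """Phenotypes y = g + e with e ~ N(0, sigma_e2)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = trait.genotypic_values(pop.dosages())
    return g + rng.normal(0.0, np.sqrt(trait.sigma_e2), size=g.size)


def enforce_maf(pop: Population, threshold: float = 0.05) -> np.ndarray:
    """Boolean mask of loci whose minor allele frequency exceeds ``threshold``."""
    if not (0.0 <= threshold <= 0.5):
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    p = pop.allele_freq()
    return np.minimum(p, 1.0 - p) > threshold


def estimate_ld(pop: Population, pairs: np.ndarray) -> np.ndarray:
    """Haplotype-based LD estimate Delta_hat = p_AB - p_A p_B for locus pairs."""
    pairs = np.asarray(pairs)
    h = pop.haplotypes.reshape(-1, pop.n_loci).astype(float)  # gametes x loci
    pA = h[:, pairs[:, 0]].mean(axis=0)
    pB = h[:, pairs[:, 1]].mean(axis=0)
    pAB = (h[:, pairs[:, 0]] * h[:, pairs[:, 1]]).mean(axis=0)
    return pAB - pA * pB


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class SimDataset:
    """One simulated replicate: cohort, trait, phenotypes and truth."""

    gmap: GenomeMap
    founders: FounderSpec
    cohort: Cohort
    trait: TraitArchitecture
    y: np.ndarray
    g: np.ndarray
    u_a: np.ndarray
    u_d: np.ndarray
    composite: Population | None = field(default=None, repr=False)

    @property
    def dosages(self) -> np.ndarray:
        return self.cohort.dosages()


def simulate_dataset(
    gmap: GenomeMap | None = None,
    founders: FounderSpec | None = None,
    composite: Population | None = None,
    trait: TraitArchitecture | None = None,
    architecture: str = "infinitesimal",
    h2_broad: float = 0.30,
    h2_narrow: float = 0.20,
    n_generations: int = 5,
    pop_size: int = 5000,
    breeding_size: int = 40,
    n_families: int = 20,
    family_size: int = 50,
    n_parents: int = 40,
    maf_threshold: float = 0.05,
    max_redraws: int = 20,
    seed=None,
) -> SimDataset:
    """Run the full simulation pipeline for one replicate.

    Replicates of the same conceptual population share the founder
    frequencies, the advanced-generation ``composite`` and the calibrated
    ``trait`` (pass the previous replicate's objects): they differ only in
    the family sampling from the composite and in the phenotype noise, so
    validation and reference individuals belong to the same population but
    to different families.  Founder frequencies of loci failing the cohort
    MAF filter are redrawn and the pipeline re-run until every marker
    passes, so the default pipeline outputs the full marker panel.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if gmap is None:
        gmap = GenomeMap.default()
    if founders is None:
        founders = FounderSpec.draw(gmap, rng)

    for _ in range(max_redraws):
        if composite is None:
            composite = simulate_composite(founders, gmap, n_generations,
                                           pop_size, rng,
                                           breeding_size=breeding_size)
        cohort = make_families(composite, gmap, n_families, family_size,
                               n_parents, rng)
        keep = enforce_maf(cohort, maf_threshold)
        if keep.all():
            break
        fresh = FounderSpec.draw(gmap, rng, scheme=founders.scheme,
                                 ne_target=founders.ne_target)
        p1, p2 = founders.p1.copy(), founders.p2.copy()
        p1[~keep], p2[~keep] = fresh.p1[~keep], fresh.p2[~keep]
        founders = FounderSpec(p1, p2, founders.scheme, founders.ne_target)
        composite = None  # re-run with the redrawn founder frequencies
    else:
        raise RuntimeError("MAF filter failed to converge; check the design")

    if trait is None:
        trait = assign_trait(
            cohort, gmap, architecture, h2_broad, h2_narrow, seed=rng
        )
    y = simulate_phenotypes(cohort, trait, rng)
    g = trait.genotypic_values(cohort.dosages())
    u_a, u_d = trait.true_components(cohort.dosages())
    return SimDataset(gmap, founders, cohort, trait, y, g, u_a, u_d, composite)
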