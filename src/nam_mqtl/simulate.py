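"""Synthetic NAM population generator.

Emulates a barley-style nested association mapping (NAM) design: ``n_families``
wild donors each crossed once to a shared elite recurrent parent, the F1
backcrossed once to the recurrent parent (BC1), followed by three generations
of selfing by single-seed descent (BC1S3).  Every downstream stage of the
pipeline (IBS coding, heritability, stepwise GWAS, mQTL reporting) can be
exercised on its output with known ground truth.

Meiosis follows the Haldane model (no crossover interference): the gamete's
founder-origin process along a chromosome is a two-state Markov chain whose
switch probability between adjacent markers at map distance ``d`` cM is the
Haldane recombination fraction ``0.5 * (1 - exp(-2 d / 100))``.  This is the
exact marginal, at the marker positions, of a Poisson crossover process with
uniform positions on the cM scale.  Chromosomes assort independently.

Under this scheme the single-locus genotype distribution in BC1S3 is exactly
P(het) = 1/16 = 6.25%, P(hom donor) = 7/32, P(hom recurrent) = 23/32, and the
expected donor genome proportion is 25%.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "FounderSet",
    "FamilyGenomes",
    "NAMPopulation",
    "QTLSpec",
    "SimTruth",
    "default_map",
    "simulate_founders",
    "simulate_bc1s3_family",
    "simulate_nam",
    "simulate_phenotypes",
    "inject_missingness_and_controls",
]


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticMap:
    """Marker map: one record per SNP with chromosome, bp and cM position.

    The underlying frame is sorted by (chromosome, bp) on construction and
    column order is ``snp_id, chrom, bp, cM``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["snp_id", "chrom", "bp", "cM"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"map is missing columns {missing}")
        if len(self.table) == 0:
            raise ValueError("empty genetic map")
        tab = (
            self.table[required]
            .sort_values(["chrom", "bp"], kind="mergesort")
            .reset_index(drop=True)
        )
        if tab["snp_id"].duplicated().any():
            raise ValueError("duplicated snp_ids in map")
        if (tab["bp"] < 1).any():
            raise ValueError("position_bp must be >= 1")
        for _, sub in tab.groupby("chrom", sort=False):
            if (np.diff(sub["cM"].to_numpy()) < -1e-9).any():
                raise ValueError("cM positions not monotone in bp within a chromosome")
        object.__setattr__(self, "table", tab)

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def chromosomes(self) -> np.ndarray:
        return np.unique(self.table["chrom"].to_numpy())

    def recombination_fractions(self) -> np.ndarray:
        """Per-SNP switch probabilities for the gamete Markov chain.

        Entry j is the recombination fraction between SNP j-1 and SNP j;
        the first SNP of every chromosome gets 0.5 (independent assortment,
        which also randomises the starting haplotype of the chain).
        """
        chrom = self.table["chrom"].to_numpy()
        cm = self.table["cM"].to_numpy(dtype=float)
        r = np.empty(len(cm))
        r[0] = 0.5
        d = np.diff(cm)
        r[1:] = 0.5 * (1.0 - np.exp(-d / 50.0))  # Haldane, d in cM
        r[1:][chrom[1:] != chrom[:-1]] = 0.5
        return r

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        return cls(pd.read_csv(path, sep="\t"))


def default_map(
    n_snps: int = 2000,
    n_chromosomes: int = 7,
    chrom_length_cm: float = 150.0,
    bp_per_cm: float = 1_000_000.0,
) -> GeneticMap:
    """Evenly spaced desk-scale map: 7 chromosomes of 150 cM by default.

    bp positions are proportional to cM (1 Mbp/cM), giving 150 Mbp
    chromosomes — compact but shaped like a cereal genome for the purposes
    of region grouping and linkage decay.
    """
    counts = np.full(n_chromosomes, n_snps // n_chromosomes)
    counts[: n_snps % n_chromosomes] += 1
    rows = []
    for c, m in enumerate(counts, start=1):
        cm = np.linspace(0.0, chrom_length_cm, int(m) + 1)[1:] - chrom_length_cm / (2 * m)
        for i, pos in enumerate(cm):
            rows.append(
                {
                    "snp_id": f"snp_{c}_{i + 1:04d}",
                    "chrom": c,
                    "bp": int(round(pos * bp_per_cm)) + 1,
                    "cM": float(pos),
                }
            )
    return GeneticMap(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FounderSet:
    """Recurrent-parent + donor haplotypes.

    The recurrent parent carries the reference allele everywhere; donors carry
    the alternative allele at an independent Bernoulli fraction of SNPs.
    ``donor_alleles[f, j] == 1`` means donor f carries the alternative allele
    at SNP j (the SNP is polymorphic within family f).
    """

    donor_alleles: np.ndarray  # (n_families, n_snps) uint8
    donor_ids: tuple

    @property
    def n_families(self) -> int:
        return self.donor_alleles.shape[0]

    @property
    def recurrent_parent(self) -> np.ndarray:
        return np.zeros(self.donor_alleles.shape[1], dtype=np.uint8)


def simulate_founders(
    n_families: int,
    gmap: GeneticMap,
    donor_polymorphism_rate: float = 0.5,
    seed: int = 0,
) -> FounderSet:
    """Draw donor haplotypes relative to an all-reference recurrent parent."""
    if n_families < 1:
        raise ValueError(f"n_families must be >= 1, got {n_families}")
    if not (0.0 < donor_polymorphism_rate <= 1.0):
        raise ValueError("donor_polymorphism_rate must be in (0, 1]")
    rng = np.random.default_rng(seed)
    alleles = (
        rng.random((n_families, gmap.n_snps)) < donor_polymorphism_rate
    ).astype(np.uint8)
    return FounderSet(
        donor_alleles=alleles,
        donor_ids=tuple(f"donor_{i + 1:02d}" for i in range(n_families)),
    )


# ---------------------------------------------------------------------------
# meiosis / family simulation
# ---------------------------------------------------------------------------

def _gametes(hap_a: np.ndarray, hap_b: np.ndarray, rfrac: np.ndarray, rng) -> np.ndarray:
    """One gamete per row of a diploid batch.

    ``hap_a``/``hap_b``: (n, m) founder-origin haplotypes; ``rfrac``: per-SNP
    switch probability (0.5 at chromosome starts).  The cumulative parity of
    switch events selects the transmitted haplotype at each SNP.
    """
    switch = rng.random(hap_a.shape) < rfrac
    phase = np.cumsum(switch, axis=1) & 1
    return np.where(phase == 1, hap_b, hap_a)


@dataclass
class FamilyGenomes:
    """Diploid founder-origin genomes for one BC1S3 family."""

    family_id: int
    line_ids: list
    origins: np.ndarray  # (n_lines, 2, n_snps) uint8; 1 = donor origin
    generation: str = "BC1S3"

    @property
    def n_lines(self) -> int:
        return self.origins.shape[0]

    @property
    def origin_dosage(self) -> np.ndarray:
        """Donor-origin allele count per line x SNP, in {0, 1, 2}."""
        return self.origins.sum(axis=1, dtype=np.int8)


def simulate_bc1s3_family(
    donor: np.ndarray,
    recurrent: np.ndarray,
    n_lines: int,
    gmap: GeneticMap,
    seed: int | None = 0,
    family_id: int = 1,
    rng=None,
) -> FamilyGenomes:
    """Simulate ``n_lines`` BC1S3 lines of one donor x recurrent family.

    F1 = donor x recurrent; BC1 = F1 x recurrent; then three selfing
    generations by single-seed descent, each line an independent lineage
    from its own BC1 plant.  ``donor``/``recurrent`` are allele vectors on
    the map (only their length is used here; genomes are tracked as founder
    origins and translated to alleles downstream).
    """
    donor = np.asarray(donor)
    recurrent = np.asarray(recurrent)
    if donor.shape != recurrent.shape or donor.shape[0] != gmap.n_snps:
        raise ValueError("donor/recurrent haplotypes must be defined on the map")
    if n_lines < 1:
        raise ValueError(f"n_lines must be >= 1, got {n_lines}")
    if rng is None:
        rng = np.random.default_rng(seed)
    m = gmap.n_snps
    rfrac = gmap.recombination_fractions()

    ones = np.ones((n_lines, m), dtype=np.uint8)
    zeros = np.zeros((n_lines, m), dtype=np.uint8)
    # BC1: gamete from the F1 (one donor + one recurrent haplotype) with a
    # recurrent-parent gamete (all reference).
    hap_a = _gametes(ones, zeros, rfrac, rng)
    hap_b = zeros
    for _ in range(3):  # S1, S2, S3 by single-seed descent
        g1 = _gametes(hap_a, hap_b, rfrac, rng)
        g2 = _gametes(hap_a, hap_b, rfrac, rng)
        hap_a, hap_b = g1, g2
    origins = np.stack([hap_a, hap_b], axis=1)
    line_ids = [f"F{family_id:02d}_L{i + 1:04d}" for i in range(n_lines)]
    return FamilyGenomes(family_id=family_id, line_ids=line_ids, origins=origins)


@dataclass
class NAMPopulation:
    """A full NAM panel: families of BC1S3 lines plus founders and map."""

    gmap: GeneticMap
    founders: FounderSet
    families: list  # list[FamilyGenomes]

    @property
    def n_lines(self) -> int:
        return sum(f.n_lines for f in self.families)

    @property
    def line_ids(self) -> list:
        return [lid for fam in self.families for lid in fam.line_ids]

    @property
    def family_labels(self) -> pd.Series:
        labels = np.concatenate(
            [np.full(f.n_lines, f.family_id) for f in self.families]
        )
        return pd.Series(labels, index=self.line_ids, name="family")

    @property
    def dosage(self) -> np.ndarray:
        """Donor-*allele* count per line x SNP (0/1/2).

        At SNPs where the family's donor carries the reference allele the
        dosage is 0 regardless of founder origin (the family is monomorphic
        there).
        """
        blocks = []
        for fam in self.families:
            allele = self.founders.donor_alleles[fam.family_id - 1]
            blocks.append(fam.origin_dosage * allele)
        return np.concatenate(blocks, axis=0)

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosage, index=self.line_ids, columns=self.gmap.snp_ids
        )

    def calls_frame(self) -> pd.DataFrame:
        """Genotype calls coded 0 = hom recurrent, 1 = het, 2 = hom donor.

        Identical to the allele dosage for fully observed simulated data.
        """
        return self.dosage_frame().astype(float)


def simulate_nam(
    n_families: int = 25,
    lines_per_family: int = 52,
    gmap: GeneticMap | None = None,
    donor_polymorphism_rate: float = 0.5,
    seed: int = 0,
) -> NAMPopulation:
    """Desk-scale NAM default: 25 families x 52 lines on a 2000-SNP map."""
    if gmap is None:
        gmap = default_map()
    ss = np.random.SeedSequence(seed)
    founder_seed, *family_seeds = ss.spawn(n_families + 1)
    founders = simulate_founders(
        n_families,
        gmap,
        donor_polymorphism_rate,
        seed=int(founder_seed.generate_state(1)[0] % (2**31)),
    )
    families = []
    for f in range(n_families):
        rng = np.random.default_rng(family_seeds[f])
        fam = simulate_bc1s3_family(
            founders.donor_alleles[f],
            founders.recurrent_parent,
            lines_per_family,
            gmap,
            family_id=f + 1,
            rng=rng,
        )
        families.append(fam)
    return NAMPopulation(gmap=gmap, founders=founders, families=families)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QTLSpec:
    """Planted QTL: additive allele-substitution effects per IBS unit.

    ``family_multipliers`` optionally scales each QTL's effect per family
    (keyed by snp_id, value = array over families, 1-based family order),
    supporting family-specific wild-allele effects.
    """

    effects: dict  # snp_id -> additive effect per IBS unit
    h2_target: float = 0.5
    family_multipliers: dict | None = None
    link: str = "identity"  # "identity" or "exp" (right-skewed, metabolite-like)
    noise: str = "normal"

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2_target <= 1.0):
            raise ValueError("h2_target must be in [0, 1]")
        if self.link not in ("identity", "exp"):
            raise ValueError(f"unknown link {self.link!r}")


@dataclass
class SimTruth:
    """Ground truth emitted by the phenotype simulator."""

    qtl: QTLSpec
    genetic_values: pd.Series
    noise_variance: float
    realized_h2: float
    family_mean_effects: pd.DataFrame  # snp x family mean effect contribution

    def to_dict(self) -> dict:
        return {
            "h2_target": self.qtl.h2_target,
            "realized_h2": float(self.realized_h2),
            "noise_variance": float(self.noise_variance),
            "qtl_effects": {k: float(v) for k, v in self.qtl.effects.items()},
            "link": self.qtl.link,
        }


def simulate_phenotypes(
    pop: NAMPopulation,
    qtl: QTLSpec,
    seed: int = 0,
    name: str = "met_1",
) -> tuple[pd.DataFrame, SimTruth]:
    """Generate one metabolite-like phenotype with known genetic architecture.

    The genetic value is ``g = sum_k effect_k * multiplier_k[family] * IBS_k``;
    the noise variance is set from the realised sample Var(g) so that
    ``Var(g) / (Var(g) + sigma_e^2)`` equals ``h2_target`` exactly.  With
    ``link="exp"`` the standardised sum is exponentiated to yield positive,
    right-skewed values (heritability then refers to the latent scale).
    """
    rng = np.random.default_rng(seed)
    dosage = pop.dosage_frame()
    fam = pop.family_labels.to_numpy()
    unknown = [s for s in qtl.effects if s not in dosage.columns]
    if unknown:
        raise ValueError(f"QTL snp_ids not in map: {unknown}")
    n = len(dosage)
    g = np.zeros(n)
    fam_effect_rows = {}
    for snp, eff in qtl.effects.items():
        mult = np.ones(pop.founders.n_families)
        if qtl.family_multipliers and snp in qtl.family_multipliers:
            mult = np.asarray(qtl.family_multipliers[snp], dtype=float)
        per_line = eff * mult[fam - 1] * dosage[snp].to_numpy(dtype=float)
        g += per_line
        fam_effect_rows[snp] = (
            pd.Series(per_line).groupby(fam).mean().to_numpy()
        )
    var_g = float(np.var(g))
    h2 = qtl.h2_target
    if h2 > 0 and var_g == 0.0:
        raise ValueError("Var(g) = 0 with h2_target > 0: cannot scale noise")
    if h2 == 0.0:
        noise_var = 1.0
        g = np.zeros(n)
        var_g = 0.0
    elif h2 == 1.0:
        noise_var = 0.0
    else:
        noise_var = var_g * (1.0 - h2) / h2
    y = g + rng.normal(0.0, np.sqrt(noise_var), size=n)
    if qtl.link == "exp":
        sd = y.std()
        y = np.exp(y / sd) if sd > 0 else np.exp(y)
    realized = var_g / (var_g + noise_var) if (var_g + noise_var) > 0 else 0.0
    table = pd.DataFrame({name: y}, index=pop.line_ids)
    truth = SimTruth(
        qtl=qtl,
        genetic_values=pd.Series(g, index=pop.line_ids, name="g"),
        noise_variance=noise_var,
        realized_h2=realized,
        family_mean_effects=pd.DataFrame(
            fam_effect_rows, index=np.arange(1, pop.founders.n_families + 1)
        ).T,
    )
    if pop.n_lines >= 1000 and abs(realized - h2) > 0.05:
        raise AssertionError(
            f"realized h2 {realized:.3f} drifted from target {h2:.3f}"
        )
    return table, truth


def inject_missingness_and_controls(
    table: pd.DataFrame,
    missing_rate: float = 0.0,
    n_controls: int = 17,
    reps_per_control: int = 4,
    seed: int = 0,
    between_sd: float = 1.0,
    within_sd: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """MCAR missingness plus replicated control genotypes.

    Controls emulate the repeated elite check lines of a field trial: each
    control has a genotype-specific mean per metabolite (spread ``between_sd``
    in units of that metabolite's SD) and ``reps_per_control`` replicate
    measurements around it (spread ``within_sd``), for repeatability
    estimation.
    """
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = table.copy()
    if missing_rate > 0:
        mask = rng.random(out.shape) < missing_rate
        vals = out.to_numpy(dtype=float)
        vals[mask] = np.nan
        out = pd.DataFrame(vals, index=out.index, columns=out.columns)
    rows = []
    for c in range(n_controls):
        means = {}
        for col in table.columns:
            col_mean = float(table[col].mean())
            col_sd = float(table[col].std())
            if not np.isfinite(col_sd) or col_sd == 0:
                col_sd = 1.0
            means[col] = col_mean + rng.normal(0.0, between_sd * col_sd)
        for r in range(reps_per_control):
            row = {"control_id": f"ctrl_{c + 1:02d}", "rep": r + 1}
            for col in table.columns:
                col_sd = float(table[col].std())
                if not np.isfinite(col_sd) or col_sd == 0:
                    col_sd = 1.0
                row[col] = means[col] + rng.normal(0.0, within_sd * col_sd)
            rows.append(row)
    controls = pd.DataFrame(rows)
    return out, controls
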