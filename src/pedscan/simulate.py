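"""Synthetic pedigrees, genotypes, and longitudinal phenotypes.

Generates data with the statistical structure the analysis pipeline
assumes: multigenerational families, unlinked biallelic markers dropped
through the pedigree from Hardy-Weinberg founder alleles (with recorded
descent, so realized IBD is known), a causal QTL plus polygenic background,
longitudinal SBP exams with sex/age/smoking covariates, and antihypertensive
medication assigned preferentially to individuals with high underlying SBP
so that it behaves as right-censoring.  Optional population stratification
assigns whole pedigrees to strata that differ in allele frequency and trait
mean.

All markers are simulated unlinked (the downstream analysis is strictly
two-point); :func:`gene_drop_linked_pair` creates a single linked marker
pair for "linked but not associated" scenarios.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ibd import MarkerGenotypes, _meiosis_layout, _sharing_from_slots, drop_slots
from .ibd import IbdMatrix
from .pedigree import Individual, Pedigree, SEX_FEMALE, SEX_MALE


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PedigreeTemplate:
    """Regular multigeneration family template.

    ``sibship_sizes[g]`` is the number of children each couple of generation
    ``g+1`` has; ``n_marry[g]`` of those children marry a founder spouse and
    form the couples of the next generation (the last generation does not
    marry).  The default (sibships 4 then 2, two marrying) gives a
    three-generation family of exactly 12 members.
    """

    sibship_sizes: tuple[int, ...] = (4, 2)
    n_marry: tuple[int, ...] = (2,)

    def __post_init__(self) -> None:
        if len(self.n_marry) != len(self.sibship_sizes) - 1:
            raise SimConfigError(
                "n_marry must have one entry per non-final sibship generation"
            )
        for s, m in zip(self.sibship_sizes, self.n_marry + (0,)):
            if s < 1 or m < 0 or m > s:
                raise SimConfigError(f"impossible template: sibship {s}, marry {m}")

    @property
    def n_generations(self) -> int:
        return len(self.sibship_sizes) + 1

    @property
    def n_members(self) -> int:
        total = 2  # founding couple
        couples = 1
        for g, size in enumerate(self.sibship_sizes):
            total += couples * size
            if g < len(self.n_marry):
                total += couples * self.n_marry[g]  # married-in spouses
                couples *= self.n_marry[g]
        return total


@dataclass
class SimConfig:
    """Study-design parameters for the generator.

    Variance fractions (``h2`` polygenic, ``qtl_frac`` for the causal
    locus) partition the non-covariate trait variance ``total_sd**2``
    (mmHg^2); the remainder is per-exam environmental noise.  ``tau`` is an
    extra pedigree-level intercept s.d.  Medication is assigned (with
    probability ``censor_prob``) to individuals whose underlying mean SBP
    exceeds the ``censor_quantile`` sample quantile, and their observed SBP
    is the underlying value minus a lognormal treatment effect.
    """

    n_pedigrees: int = 20
    template: PedigreeTemplate = field(default_factory=PedigreeTemplate)
    n_exams: int = 3
    mean_sbp: float = 120.0
    total_sd: float = 15.0
    h2: float = 0.3
    qtl_frac: float = 0.0
    qtl_maf: float = 0.2
    tau: float = 5.0
    beta_sex: float = -4.0  # female relative to male, mmHg
    beta_age: float = 0.4  # mmHg per year
    beta_smoke: float = 3.0
    smoking_rate: float = 0.2
    exam_spacing_years: float = 5.0
    censor_quantile: float = 0.7
    censor_prob: float = 1.0
    treatment_mu_log: float = 2.3  # lognormal drop, median ~10 mmHg
    treatment_sigma_log: float = 0.4
    censor_mechanism: str = "threshold"  # or "subtractive"
    censor_sd: float = 8.0  # spread of the treated observed level, mmHg
    n_strata: int = 1
    strata_freq_divergence: float = 0.0
    strata_mean_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2 <= 1.0 and 0.0 <= self.qtl_frac <= 1.0):
            raise SimConfigError("variance fractions must lie in [0, 1]")
        if self.h2 + self.qtl_frac > 1.0:
            raise SimConfigError(
                f"variance budget exceeded: h2 + qtl_frac = {self.h2 + self.qtl_frac}"
            )
        if not 0.0 < self.qtl_maf <= 0.5:
            raise SimConfigError("qtl_maf must be in (0, 0.5]")
        if self.censor_mechanism not in ("threshold", "subtractive"):
            raise SimConfigError(
                "censor_mechanism must be 'threshold' or 'subtractive'"
            )

    @property
    def sigma2_a(self) -> float:
        return self.h2 * self.total_sd ** 2

    @property
    def sigma2_qtl(self) -> float:
        return self.qtl_frac * self.total_sd ** 2

    @property
    def sigma2_e(self) -> float:
        return (1.0 - self.h2 - self.qtl_frac) * self.total_sd ** 2

    @property
    def qtl_beta(self) -> float:
        """Allelic effect implied by qtl_frac at qtl_maf, trait units/allele."""
        if self.qtl_frac == 0.0:
            return 0.0
        return float(
            np.sqrt(self.sigma2_qtl / (2.0 * self.qtl_maf * (1.0 - self.qtl_maf)))
        )


@dataclass
class SimTruth:
    """Generative ground truth retained for tests and diagnostics."""

    # marker -> family -> (n_members, 2) founder-slot labels per allele
    descent: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    # marker -> family -> founder allele values (0/1 minor) per slot
    founder_alleles: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    member_ids: dict[str, tuple[str, ...]] = field(default_factory=dict)
    genetic_value: dict[str, float] = field(default_factory=dict)
    true_sbp: pd.DataFrame | None = None  # id, exam, sbp_true
    medicated: set[str] = field(default_factory=set)
    qtl_marker_id: str | None = None
    qtl_beta: float = 0.0
    stratum_of_family: dict[str, int] = field(default_factory=dict)

    def realized_ibd(self, marker_id: str, family_id: str) -> IbdMatrix:
        """Realized IBD sharing implied by the recorded descent paths."""
        slots = self.descent[marker_id][family_id]
        values = _sharing_from_slots(slots[None])[0]
        return IbdMatrix(self.member_ids[family_id], values, marker_id, family_id)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genetic_value": self.genetic_value,
            "medicated": sorted(self.medicated),
            "qtl_marker_id": self.qtl_marker_id,
            "qtl_beta": self.qtl_beta,
            "stratum_of_family": self.stratum_of_family,
            "descent": {
                m: {f: s.tolist() for f, s in fams.items()}
                for m, fams in self.descent.items()
            },
            "true_sbp": None
            if self.true_sbp is None
            else self.true_sbp.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload))


# --------------------------------------------------------------------------
# pedigree structure
# --------------------------------------------------------------------------

def simulate_pedigrees(
    n_pedigrees: int, template: PedigreeTemplate | None = None
) -> list[Pedigree]:
    """Build ``n_pedigrees`` families from a deterministic template.

    Structure (and sexes, which alternate within sibships) is fully
    determined by the template, so no seed is involved.
    """
    template = template or PedigreeTemplate()
    peds = []
    for k in range(n_pedigrees):
        fam = f"P{k + 1:02d}"
        serial = [0]

        def new_id() -> str:
            serial[0] += 1
            return f"{fam}_{serial[0]:03d}"

        members: list[Individual] = []

        def add(father, mother, sex) -> str:
            iid = new_id()
            members.append(Individual(iid, fam, father, mother, sex))
            return iid

        pa = add(None, None, SEX_MALE)
        ma = add(None, None, SEX_FEMALE)
        couples = [(pa, ma)]
        for g, size in enumerate(template.sibship_sizes):
            next_couples = []
            for father, mother in couples:
                kids = [
                    add(father, mother, SEX_MALE if i % 2 == 0 else SEX_FEMALE)
                    for i in range(size)
                ]
                if g < len(template.n_marry):
                    for kid_id in kids[: template.n_marry[g]]:
                        kid = next(m for m in members if m.individual_id == kid_id)
                        spouse_sex = (
                            SEX_FEMALE if kid.sex == SEX_MALE else SEX_MALE
                        )
                        spouse = add(None, None, spouse_sex)
                        if kid.sex == SEX_MALE:
                            next_couples.append((kid_id, spouse))
                        else:
                            next_couples.append((spouse, kid_id))
            couples = next_couples
        peds.append(Pedigree(members))
    return peds


# --------------------------------------------------------------------------
# genotypes
# --------------------------------------------------------------------------

def _drop_one_marker(
    ped: Pedigree, maf: float, rng: np.random.Generator
) -> tuple[dict[str, int], np.ndarray, np.ndarray]:
    _, meioses = _meiosis_layout(ped)
    bits = rng.integers(0, 2, size=(1, len(meioses)), dtype=np.int8)
    slots = drop_slots(ped, bits)[0]  # (n, 2)
    n_slots = 2 * len(ped.founders)
    alleles = (rng.random(n_slots) < maf).astype(np.int8)
    dosage = alleles[slots[:, 0]] + alleles[slots[:, 1]]
    geno = {iid: int(d) for iid, d in zip(ped.ids, dosage)}
    return geno, slots, alleles


def gene_drop(
    peds: Sequence[Pedigree],
    mafs: Sequence[float],
    seed: int,
    chromosome: str = "3",
    positions: Sequence[int] | None = None,
    marker_prefix: str = "m",
    maf_by_stratum: dict[int, Sequence[float]] | None = None,
    stratum_of_family: dict[str, int] | None = None,
    truth: SimTruth | None = None,
) -> tuple[list[MarkerGenotypes], SimTruth]:
    """Drop unlinked markers through the pedigrees, recording descent.

    Founder alleles are Hardy-Weinberg draws at each marker's ``maf`` (or
    the stratum-specific frequency when ``maf_by_stratum`` is given);
    transmissions are fair Mendelian coin flips.  Descent paths and founder
    allele values go into the returned :class:`SimTruth`.
    """
    for m in mafs:
        if not 0.0 < m <= 0.5:
            raise SimConfigError(f"maf {m} outside (0, 0.5]")
    rng = np.random.default_rng(seed)
    truth = truth or SimTruth()
    for ped in peds:
        truth.member_ids[ped.family_id] = ped.ids
    if positions is None:
        positions = [1_000_000 + 50_000 * i for i in range(len(mafs))]
    markers = []
    for i, maf in enumerate(mafs):
        mid = f"{marker_prefix}{i:05d}"
        dosages: dict[str, int] = {}
        truth.descent[mid] = {}
        truth.founder_alleles[mid] = {}
        for ped in peds:
            f_maf = maf
            if maf_by_stratum is not None and stratum_of_family is not None:
                f_maf = maf_by_stratum[stratum_of_family[ped.family_id]][i]
            geno, slots, alleles = _drop_one_marker(ped, f_maf, rng)
            dosages.update(geno)
            truth.descent[mid][ped.family_id] = slots
            truth.founder_alleles[mid][ped.family_id] = alleles
        markers.append(
            MarkerGenotypes(mid, chromosome, int(positions[i]), dosages, maf=maf)
        )
    return markers, truth


def gene_drop_linked_pair(
    peds: Sequence[Pedigree],
    maf_a: float,
    maf_b: float,
    recomb: float = 0.0,
    seed: int = 0,
    chromosome: str = "3",
    positions: tuple[int, int] = (1_000_000, 1_050_000),
) -> tuple[MarkerGenotypes, MarkerGenotypes, SimTruth]:
    """Two markers sharing descent up to recombination fraction ``recomb``.

    Founder allele values are drawn independently at the two markers, so
    marker B cosegregates with (is linked to) marker A without being
    associated with A's alleles in the population.
    """
    rng = np.random.default_rng(seed)
    truth = SimTruth()
    dos_a: dict[str, int] = {}
    dos_b: dict[str, int] = {}
    truth.descent["A"] = {}
    truth.descent["B"] = {}
    truth.founder_alleles["A"] = {}
    truth.founder_alleles["B"] = {}
    for ped in peds:
        truth.member_ids[ped.family_id] = ped.ids
        _, meioses = _meiosis_layout(ped)
        bits_a = rng.integers(0, 2, size=(1, len(meioses)), dtype=np.int8)
        flips = (rng.random((1, len(meioses))) < recomb).astype(np.int8)
        bits_b = bits_a ^ flips
        slots_a = drop_slots(ped, bits_a)[0]
        slots_b = drop_slots(ped, bits_b)[0]
        n_slots = 2 * len(ped.founders)
        all_a = (rng.random(n_slots) < maf_a).astype(np.int8)
        all_b = (rng.random(n_slots) < maf_b).astype(np.int8)
        for i, iid in enumerate(ped.ids):
            dos_a[iid] = int(all_a[slots_a[i, 0]] + all_a[slots_a[i, 1]])
            dos_b[iid] = int(all_b[slots_b[i, 0]] + all_b[slots_b[i, 1]])
        truth.descent["A"][ped.family_id] = slots_a
        truth.descent["B"][ped.family_id] = slots_b
        truth.founder_alleles["A"][ped.family_id] = all_a
        truth.founder_alleles["B"][ped.family_id] = all_b
    ma = MarkerGenotypes("A", chromosome, positions[0], dos_a, maf=maf_a)
    mb = MarkerGenotypes("B", chromosome, positions[1], dos_b, maf=maf_b)
    return ma, mb, truth


# --------------------------------------------------------------------------
# phenotypes
# --------------------------------------------------------------------------

def simulate_phenotypes(
    peds: Sequence[Pedigree],
    truth: SimTruth,
    cfg: SimConfig,
    kinships: dict | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Longitudinal exam records under the generative trait model.

    Underlying SBP at exam *e*:

        mean + stratum shift + beta_sex*female + beta_age*age_e +
        beta_smoke*smoke + beta_qtl*(dosage - 2*maf) + polygenic + u_ped +
        exam noise

    with polygenic values MVN(0, 2*Phi*sigma2_a) per pedigree.  Medication
    then right-censors the trait: under the default "threshold" mechanism a
    record is medicated when the underlying value exceeds the individual's
    random treatment level and the treated level is what is observed
    (noninformative censoring, matching the adjustment model); the
    "subtractive" mechanism instead subtracts a positive lognormal
    treatment effect from the underlying value.  Either way medication
    concentrates in high underlying SBP and observed < underlying.
    Genetic values, underlying SBP, and medication sets are written into
    ``truth``.
    """
    from .pedigree import compute_kinship

    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if cfg.qtl_frac > 0.0:
        if truth.qtl_marker_id is None:
            raise SimConfigError(
                "qtl_frac > 0 requires truth.qtl_marker_id to name the causal marker"
            )
    beta_qtl = cfg.qtl_beta
    truth.qtl_beta = beta_qtl

    rows = []
    base_age_by_gen = {0: 62.0, 1: 40.0, 2: 20.0, 3: 20.0}
    for ped in peds:
        kin = (kinships or {}).get(ped.family_id)
        if kin is None:
            kin = compute_kinship(ped)
        n = len(ped)
        stratum = truth.stratum_of_family.get(ped.family_id, 0)
        shift = cfg.strata_mean_shift * stratum
        # polygenic values: MVN(0, 2 Phi sigma2_a)
        if cfg.sigma2_a > 0:
            L = np.linalg.cholesky(kin.matrix2 + 1e-10 * np.eye(n))
            a = L @ rng.standard_normal(n) * np.sqrt(cfg.sigma2_a)
        else:
            a = np.zeros(n)
        u_ped = rng.normal(0.0, cfg.tau)
        # generation depth for age assignment
        depth = {}
        for m in ped.members:
            depth[m.individual_id] = (
                0 if m.is_founder else depth[m.father_id] + 1
            )
        # married-in founders share their spouse's generation
        for m in ped.members:
            if not m.is_founder:
                d = depth[m.individual_id] - 1
                for pid in (m.father_id, m.mother_id):
                    if ped[pid].is_founder:
                        depth[pid] = d
        smoke = rng.random(n) < cfg.smoking_rate
        base_age = np.array(
            [
                base_age_by_gen.get(depth[m.individual_id], 20.0)
                + rng.normal(0.0, 3.0)
                for m in ped.members
            ]
        )
        if cfg.qtl_frac > 0.0:
            marker = truth.qtl_marker_id
            slots = truth.descent[marker][ped.family_id]
            alleles = truth.founder_alleles[marker][ped.family_id]
            dosage = alleles[slots[:, 0]] + alleles[slots[:, 1]]
            qtl_term = beta_qtl * (dosage - 2.0 * cfg.qtl_maf)
        else:
            qtl_term = np.zeros(n)
        female = np.array([m.sex == SEX_FEMALE for m in ped.members], float)
        for i, m in enumerate(ped.members):
            truth.genetic_value[m.individual_id] = float(a[i] + qtl_term[i])
        for e in range(1, cfg.n_exams + 1):
            age = base_age + cfg.exam_spacing_years * (e - 1)
            eps = rng.normal(0.0, np.sqrt(cfg.sigma2_e), n)
            sbp_true = (
                cfg.mean_sbp
                + shift
                + cfg.beta_sex * female
                + cfg.beta_age * age
                + cfg.beta_smoke * smoke
                + qtl_term
                + a
                + u_ped
                + eps
            )
            for i, m in enumerate(ped.members):
                rows.append(
                    {
                        "id": m.individual_id,
                        "exam": e,
                        "sbp_true": sbp_true[i],
                        "age": age[i],
                        "sex": "female" if female[i] else "male",
                        "smoke": "yes" if smoke[i] else "no",
                    }
                )
    df = pd.DataFrame(rows)

    if cfg.censor_prob > 0.0 and cfg.censor_quantile < 1.0:
        if cfg.censor_mechanism == "threshold":
            # noninformative right-censoring: each individual carries a
            # treatment level C (independent of their trait given covariates,
            # centered at the censor_quantile of the underlying distribution);
            # a record is medicated iff the underlying value exceeds C, and
            # the treated observation IS C.
            cut = float(df["sbp_true"].quantile(cfg.censor_quantile))
            ids = df["id"].unique()
            eligible = rng.random(len(ids)) < cfg.censor_prob
            level = cut + rng.normal(0.0, cfg.censor_sd, len(ids))
            c_of = {
                i: (level[k] if eligible[k] else np.inf)
                for k, i in enumerate(ids)
            }
            c_vec = df["id"].map(c_of).to_numpy(float)
            med = df["sbp_true"].to_numpy() > c_vec
            df["med"] = np.where(med, "yes", "no")
            df["sbp"] = np.where(med, c_vec, df["sbp_true"])
        else:
            # subtractive: medicated individuals (top of the underlying
            # distribution) observe true value minus a lognormal treatment
            # drop; the treated observation then still carries information
            # about the underlying value beyond the censoring bound
            mean_sbp = df.groupby("id")["sbp_true"].mean()
            cut = mean_sbp.quantile(cfg.censor_quantile)
            high = mean_sbp.index[mean_sbp > cut]
            take = rng.random(len(high)) < cfg.censor_prob
            med_ids = set(np.asarray(high)[take])
            df["med"] = df["id"].map(lambda i: "yes" if i in med_ids else "no")
            drop = np.where(
                df["med"].to_numpy() == "yes",
                rng.lognormal(
                    cfg.treatment_mu_log, cfg.treatment_sigma_log, len(df)
                ),
                0.0,
            )
            df["sbp"] = df["sbp_true"] - drop
    else:
        df["med"] = "no"
        df["sbp"] = df["sbp_true"]

    truth.medicated = set(df.loc[df["med"] == "yes", "id"])
    truth.true_sbp = df[["id", "exam", "sbp_true"]].copy()
    return df[["id", "exam", "sbp", "age", "sex", "smoke", "med"]]


def assign_strata(
    peds: Sequence[Pedigree], n_strata: int, truth: SimTruth
) -> dict[str, int]:
    """Assign whole pedigrees round-robin to strata (family-based sampling)."""
    out = {ped.family_id: k % n_strata for k, ped in enumerate(peds)}
    truth.stratum_of_family = out
    return out


def stratified_freqs(
    base_mafs: Sequence[float], divergence: float, n_strata: int = 2
) -> dict[int, list[float]]:
    """Per-stratum allele frequencies: stratum s gets maf + s*divergence (clipped)."""
    return {
        s: [float(np.clip(m + s * divergence, 0.01, 0.99)) for m in base_mafs]
        for s in range(n_strata)
    }
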