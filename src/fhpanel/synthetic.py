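"""Synthetic cohorts and annotated variant call sets.

Everything downstream of sequencing is testable without any external data:
this module fabricates (a) case-control cohort tables with the marginal
structure of the validation study (338 high-LDL cases vs 339 low-LDL
controls, binary covariates reproducing printed 2x2 counts exactly in
*exact* mode, or drawn per-group Bernoulli/Normal in *stochastic* mode),
(b) genotype vectors with a planted per-genotype odds ratio against
Hardy-Weinberg controls, and (c) discovery-style call sets (25 vs 25
carriers) with case-exclusive planted variants across the three FH gene
tiers plus decoys that each violate exactly one cascade filter.

Case genotypes are drawn by exact retrospective tilting: the case genotype
distribution is the control (HWE) distribution re-weighted by the target
odds ratio per genotype and renormalized.  This is the retrospective-
likelihood counterpart of injecting the effect through a logistic disease
model and makes the case-vs-control per-genotype odds ratio equal the
requested value exactly in expectation, while the control arm stays
Hardy-Weinberg at the stated MAF.

All generators take one seed and use a single ``numpy.random.Generator``
per call; identical spec + seed reproduces byte-identical output.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import BINARY_COVARIATES, GT_PREFIX

__all__ = [
    "BinaryCovariateSpec",
    "ContinuousCovariateSpec",
    "CohortSpec",
    "GenotypeSpec",
    "PlantSpec",
    "CallsetPlan",
    "Callset",
    "generate_cohort",
    "generate_genotypes",
    "generate_callset",
    "write_callset",
    "table1_cohort_spec",
    "TABLE1_BINARY_COUNTS",
    "TABLE1_CONTINUOUS",
    "DISCOVERY_SAMPLES",
]


# ---------------------------------------------------------------------------
# cohort specs

@dataclass(frozen=True)
class BinaryCovariateSpec:
    """One tristate (yes/no/missing) covariate.

    Exact mode fixes the four cell counts (missing = group size minus
    yes+no); stochastic mode draws Bernoulli(p) per group with an optional
    missingness rate applied after value generation.
    """

    case_yes: int | None = None
    case_no: int | None = None
    control_yes: int | None = None
    control_no: int | None = None
    p_case: float | None = None
    p_control: float | None = None
    missing_rate: float = 0.0

    @property
    def exact(self) -> bool:
        return self.case_yes is not None

    def validate(self, n_case: int, n_control: int, name: str) -> None:
        if self.exact:
            for label, yes, no, n in (
                ("case", self.case_yes, self.case_no, n_case),
                ("control", self.control_yes, self.control_no, n_control),
            ):
                if yes is None or no is None or yes < 0 or no < 0:
                    raise ValueError(f"{name}: incomplete exact counts for {label}s")
                if yes + no > n:
                    raise ValueError(
                        f"{name}: {label} counts {yes}+{no} exceed group size {n}"
                    )
        else:
            for label, p in (("p_case", self.p_case), ("p_control", self.p_control)):
                if p is None or not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}: {label} must be a probability, got {p}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"{name}: missing_rate must be in [0, 1)")


@dataclass(frozen=True)
class ContinuousCovariateSpec:
    """Per-group Normal(mean, sd), truncated to ``bounds`` by rejection."""

    case_mean: float = 0.0
    case_sd: float = 1.0
    control_mean: float = 0.0
    control_sd: float = 1.0
    bounds: tuple[float, float] = (-np.inf, np.inf)

    def validate(self, name: str) -> None:
        if self.case_sd <= 0 or self.control_sd <= 0:
            raise ValueError(f"{name}: standard deviations must be positive")
        if not self.bounds[0] < self.bounds[1]:
            raise ValueError(f"{name}: bounds must be ordered")


@dataclass(frozen=True)
class GenotypeSpec:
    """A planted biallelic genotype effect.

    ``effect_or`` is the per-genotype odds ratio of each non-reference
    genotype against homozygous reference (``genotypic`` model) or the
    per-allele odds ratio compounded per copy (``additive`` model,
    OR(k copies) = effect_or**k).  Controls follow Hardy-Weinberg at
    ``maf`` unless explicit ``genotype_probs`` are supplied with
    ``hwe=False``.
    """

    maf: float = 0.1
    effect_or: float = 1.0
    model: str = "genotypic"
    hwe: bool = True
    genotype_probs: tuple[float, float, float] | None = None
    seed: int | None = None

    def validate(self) -> None:
        if not 0.0 < self.maf < 1.0:
            raise ValueError(f"maf must be in (0, 1), got {self.maf}")
        if self.effect_or <= 0:
            raise ValueError(f"effect_or must be positive, got {self.effect_or}")
        if self.model not in ("genotypic", "additive"):
            raise ValueError(f"unknown genetic model {self.model!r}")
        if not self.hwe and self.genotype_probs is None:
            raise ValueError("hwe=False requires explicit genotype_probs")

    def control_probs(self) -> np.ndarray:
        if self.hwe:
            q = self.maf
            return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
        p = np.asarray(self.genotype_probs, dtype=float)
        if p.shape != (3,) or not np.isclose(p.sum(), 1.0) or (p < 0).any():
            raise ValueError("genotype_probs must be 3 non-negative values summing to 1")
        return p

    def genotype_odds_ratios(self) -> np.ndarray:
        if self.model == "genotypic":
            return np.array([1.0, self.effect_or, self.effect_or])
        return np.array([1.0, self.effect_or, self.effect_or**2])


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic case-control cohort table."""

    n_case: int = 338
    n_control: int = 339
    binary: dict[str, BinaryCovariateSpec] = field(default_factory=dict)
    continuous: dict[str, ContinuousCovariateSpec] = field(default_factory=dict)
    sex: BinaryCovariateSpec | None = None  # yes == male
    genotypes: dict[str, GenotypeSpec] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValueError("group sizes must be positive")
        for name, spec in self.binary.items():
            spec.validate(self.n_case, self.n_control, name)
        if self.sex is not None:
            self.sex.validate(self.n_case, self.n_control, "sex")
        for name, spec in self.continuous.items():
            spec.validate(name)
        for spec in self.genotypes.values():
            spec.validate()


# ---------------------------------------------------------------------------
# validation-cohort defaults (exact 2x2 marginals of the 677-participant arm)

#: (case_yes, case_no, control_yes, control_no) per covariate; missing cells
#: are implied by the group sizes 338 / 339.
TABLE1_BINARY_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "tobacco_ever": (102, 228, 70, 260),
    "stroke_history": (3, 334, 7, 332),
    "angina_mi_history": (11, 326, 11, 328),
    "heart_failure_history": (7, 330, 11, 328),
    "obesity_on_medication": (26, 311, 36, 303),
    "htn_on_medication": (113, 224, 127, 212),
    "dm_on_medication": (55, 282, 81, 258),
    "famhx_htn": (106, 231, 118, 221),
    "famhx_dm": (86, 251, 92, 247),
    "famhx_stroke": (29, 308, 40, 299),
    "famhx_angina": (18, 319, 10, 329),
    "famhx_hyperlipidemia": (21, 316, 9, 330),
    "famhx_heart_disease": (42, 295, 31, 308),
    "famhx_cvd": (76, 261, 71, 268),
}

#: (case_mean, case_sd, control_mean, control_sd, bounds)
TABLE1_CONTINUOUS: dict[str, tuple[float, float, float, float, tuple[float, float]]] = {
    # ages restricted to the cohort's 35-70 inclusion window
    "age_years": (53.36, 6.36, 51.63, 6.45, (35.0, 70.0)),
    # printed unit label is inconsistent across tables; values are mmol/L
    "fasting_glucose_mmol_l": (7.15, 3.62, 6.51, 2.79, (2.0, 30.0)),
    "bmi_kg_m2": (26.71, 4.15, 26.65, 5.19, (14.0, 60.0)),
}

_TABLE1_SEX = (134, 204, 113, 226)  # male/female counts, case then control


def table1_cohort_spec(
    mode: str = "exact",
    seed: int = 0,
    genotypes: dict[str, GenotypeSpec] | None = None,
) -> CohortSpec:
    """The validation-cohort recipe (338 HLDL vs 339 LLDL).

    ``mode="exact"`` reproduces every printed 2x2 cell bit-for-bit
    (including the per-covariate missing counts implied by the varying
    denominators); ``mode="stochastic"`` converts the same marginals to
    per-group Bernoulli probabilities and missingness rates.
    """
    if mode not in ("exact", "stochastic"):
        raise ValueError(f"unknown mode {mode!r}")
    n_case, n_control = 338, 339
    binary: dict[str, BinaryCovariateSpec] = {}
    for name, (a, b, c, d) in TABLE1_BINARY_COUNTS.items():
        if mode == "exact":
            binary[name] = BinaryCovariateSpec(
                case_yes=a, case_no=b, control_yes=c, control_no=d
            )
        else:
            miss = 1.0 - (a + b + c + d) / (n_case + n_control)
            binary[name] = BinaryCovariateSpec(
                p_case=a / (a + b), p_control=c / (c + d), missing_rate=max(miss, 0.0)
            )
    sm, sf, cm, cf = _TABLE1_SEX
    sex = (
        BinaryCovariateSpec(case_yes=sm, case_no=sf, control_yes=cm, control_no=cf)
        if mode == "exact"
        else BinaryCovariateSpec(p_case=sm / (sm + sf), p_control=cm / (cm + cf))
    )
    continuous = {
        name: ContinuousCovariateSpec(m1, s1, m0, s0, bounds)
        for name, (m1, s1, m0, s0, bounds) in TABLE1_CONTINUOUS.items()
    }
    return CohortSpec(
        n_case=n_case,
        n_control=n_control,
        binary=binary,
        continuous=continuous,
        sex=sex,
        genotypes=dict(genotypes or {}),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cohort generation

def _binary_column(
    spec: BinaryCovariateSpec, n: int, p: float | None, yes: int | None,
    no: int | None, rng: np.random.Generator,
    levels: tuple[str, str] = ("yes", "no"),
) -> np.ndarray:
    if spec.exact:
        values = np.array(
            [levels[0]] * yes + [levels[1]] * no + [""] * (n - yes - no), dtype=object
        )
        return rng.permutation(values)
    values = np.where(rng.random(n) < p, levels[0], levels[1]).astype(object)
    if spec.missing_rate > 0:
        values[rng.random(n) < spec.missing_rate] = ""
    return values


def _truncated_normal(
    n: int, mean: float, sd: float, bounds: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    out = rng.normal(mean, sd, size=n)
    bad = (out < bounds[0]) | (out > bounds[1])
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < bounds[0]) | (out > bounds[1])
    return out


def _group_lipids(n: int, group: str, rng: np.random.Generator) -> pd.DataFrame:
    """Lipid panels consistent with the arm's selection window."""
    if group == "HLDL":
        ldl = _truncated_normal(n, 5.8, 0.7, (4.95, 10.0), rng)
        tc = ldl + _truncated_normal(n, 2.6, 0.5, (1.0, 6.0), rng)
        tc = np.maximum(tc, 7.55)
    else:
        ldl = _truncated_normal(n, 3.0, 0.2, (2.6, 3.4), rng)
        tc = ldl + _truncated_normal(n, 1.6, 0.25, (0.6, 2.1), rng)
        tc = np.minimum(tc, 5.15)
    hdl = _truncated_normal(n, 1.3, 0.3, (0.5, 3.0), rng)
    tg = _truncated_normal(n, 1.6, 0.7, (0.3, 6.0), rng)
    return pd.DataFrame(
        {"tc_mmol_l": tc, "ldl_mmol_l": ldl, "hdl_mmol_l": hdl, "tg_mmol_l": tg}
    )


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Generate a cohort table from a :class:`CohortSpec`.

    Exact-mode binary covariates reproduce the requested cell counts
    bit-for-bit (values shuffled within group); stochastic mode draws
    per-group Bernoulli/Normal.  Missingness is applied after value
    generation.  Identical spec + seed gives an identical table.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    frames = []
    for group, n in (("HLDL", spec.n_case), ("LLDL", spec.n_control)):
        is_case = group == "HLDL"
        width = len(str(max(spec.n_case, spec.n_control)))
        prefix = "H" if is_case else "L"
        df = pd.DataFrame(
            {"id": [f"{prefix}{i + 1:0{width}d}" for i in range(n)], "group": group}
        )
        df["age_years"] = np.nan  # placeholder order; filled below
        for name, cspec in spec.continuous.items():
            mean, sd = (
                (cspec.case_mean, cspec.case_sd)
                if is_case
                else (cspec.control_mean, cspec.control_sd)
            )
            df[name] = _truncated_normal(n, mean, sd, cspec.bounds, rng)
        sex_spec = spec.sex or BinaryCovariateSpec(p_case=0.5, p_control=0.5)
        df["sex"] = _binary_column(
            sex_spec,
            n,
            sex_spec.p_case if is_case else sex_spec.p_control,
            sex_spec.case_yes if is_case else sex_spec.control_yes,
            sex_spec.case_no if is_case else sex_spec.control_no,
            rng,
            levels=("male", "female"),
        )
        df = pd.concat([df, _group_lipids(n, group, rng)], axis=1)
        for name, bspec in spec.binary.items():
            df[name] = _binary_column(
                bspec,
                n,
                bspec.p_case if is_case else bspec.p_control,
                bspec.case_yes if is_case else bspec.control_yes,
                bspec.case_no if is_case else bspec.control_no,
                rng,
            )
        frames.append(df)
    cohort = pd.concat(frames, ignore_index=True)
    for name in BINARY_COVARIATES:
        if name not in cohort.columns:
            cohort[name] = "no"
    for name in ("age_years", "fasting_glucose_mmol_l", "bmi_kg_m2"):
        if name not in spec.continuous:
            cohort[name] = np.nan
    labels = (cohort["group"] == "HLDL").to_numpy().astype(int)
    for vid, gspec in spec.genotypes.items():
        counts = _draw_genotypes(labels, gspec, rng)
        cohort[GT_PREFIX + vid] = np.array(["ref", "het", "hom"], dtype=object)[counts]
    if "age_years" not in spec.continuous:
        cohort = cohort.drop(columns=["age_years"])
    return cohort


# ---------------------------------------------------------------------------
# genotypes

def _draw_genotypes(
    labels: np.ndarray, spec: GenotypeSpec, rng: np.random.Generator
) -> np.ndarray:
    p_control = spec.control_probs()
    weights = p_control * spec.genotype_odds_ratios()
    p_case = weights / weights.sum()
    out = np.empty(labels.shape[0], dtype=np.int64)
    is_case = labels == 1
    out[is_case] = rng.choice(3, size=int(is_case.sum()), p=p_case)
    out[~is_case] = rng.choice(3, size=int((~is_case).sum()), p=p_control)
    return out


def generate_genotypes(
    n_case: int, n_control: int, spec: GenotypeSpec, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw genotype copy counts (0/1/2) and case labels (1 = case).

    Controls are Hardy-Weinberg at ``spec.maf``; cases are drawn from the
    tilted distribution so the per-genotype case-vs-control odds ratio
    equals ``spec.effect_or`` (genotypic) or ``effect_or**k`` (additive).
    """
    if n_case <= 0 or n_control <= 0:
        raise ValueError("group sizes must be positive")
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    labels = np.concatenate([np.ones(n_case, dtype=int), np.zeros(n_control, dtype=int)])
    genotypes = _draw_genotypes(labels, spec, rng)
    return genotypes, labels


# ---------------------------------------------------------------------------
# call sets

#: discovery-arm sample names: 25 high-LDL (H*) and 25 low-LDL (L*).
DISCOVERY_SAMPLES: dict[str, str] = {
    **{f"H{i:02d}": "HLDL" for i in range(1, 26)},
    **{f"L{i:02d}": "LLDL" for i in range(1, 26)},
}

_TIER_GENES = {
    1: ["LDLR", "APOB", "PCSK9", "LDLRAP1"],
    2: ["NYNRIN", "CELSR2", "PARP10", "MAF1", "OSBPL7",
        "DCPS", "GPAA1", "LPA", "OPLAH", "SPATC1"],
    3: ["WDR74", "FRG1BP", "SEC13", "KEAP1", "GLMP", "MUC12", "UBR1",
        "GBP7", "RNF212", "DPCR1", "HEATR5A", "TIMELESS", "GTF3C1"],
}
_GENE_CHROM = {
    "LDLR": "19", "APOB": "2", "PCSK9": "1", "LDLRAP1": "1",
    "NYNRIN": "14", "CELSR2": "1", "PARP10": "8", "MAF1": "8", "OSBPL7": "17",
    "DCPS": "11", "GPAA1": "8", "LPA": "6", "OPLAH": "8", "SPATC1": "8",
    "WDR74": "11", "FRG1BP": "20", "SEC13": "3", "KEAP1": "19", "GLMP": "1",
    "MUC12": "7", "UBR1": "15", "GBP7": "1", "RNF212": "4", "DPCR1": "6",
    "HEATR5A": "14", "TIMELESS": "12", "GTF3C1": "16",
}

#: ANNOVAR-style raw strings written to the annotation TSV, keyed by the
#: internal functional class (the variants module harmonizes them back).
_RAW_FUNC = {
    "nonsynonymous_snv": "nonsynonymous SNV",
    "synonymous_snv": "synonymous SNV",
    "stopgain_snv": "stopgain",
    "stoploss_snv": "stoploss",
    "frameshift_del": "frameshift deletion",
    "frameshift_ins": "frameshift insertion",
    "nonframeshift_sub": "nonframeshift substitution",
    "nonframeshift_del": "nonframeshift deletion",
    "nonframeshift_ins": "nonframeshift insertion",
    "non_exonic": "intronic",
}

DECOY_KINDS = ("synonymous", "tolerated", "shared", "intronic")


@dataclass(frozen=True)
class PlantSpec:
    """Planted case- or control-exclusive variants for one tier."""

    tier: int
    direction: str  # risk_increasing | risk_reducing
    n_variants: int
    carriers: int  # carriers in the exclusive group, per variant

    def validate(self, n_hldl: int, n_lldl: int) -> None:
        if self.tier not in (1, 2, 3):
            raise ValueError(f"tier must be 1, 2 or 3, got {self.tier}")
        if self.direction not in ("risk_increasing", "risk_reducing"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.n_variants < 0 or self.carriers < 0:
            raise ValueError("counts must be non-negative")
        group_n = n_hldl if self.direction == "risk_increasing" else n_lldl
        if self.carriers > group_n:
            raise ValueError(
                f"carrier count {self.carriers} exceeds group size {group_n}"
            )


@dataclass(frozen=True)
class CallsetPlan:
    """Recipe for a discovery-style call set with known ground truth."""

    planted: tuple[PlantSpec, ...] = ()
    decoys: dict[str, int] = field(default_factory=dict)
    n_hldl: int = 25
    n_lldl: int = 25
    seed: int = 0

    def validate(self) -> None:
        if self.n_hldl <= 0 or self.n_lldl <= 0:
            raise ValueError("group sizes must be positive")
        for p in self.planted:
            p.validate(self.n_hldl, self.n_lldl)
        for kind, count in self.decoys.items():
            if kind not in DECOY_KINDS:
                raise ValueError(f"unknown decoy kind {kind!r}; use {DECOY_KINDS}")
            if count < 0:
                raise ValueError("decoy counts must be non-negative")


@dataclass
class Callset:
    """A generated call set: VCF text, annotation table, and ground truth."""

    vcf_text: str
    annotation: pd.DataFrame
    truth: pd.DataFrame
    sample_groups: dict[str, str]


_BASES = "ACGT"


def _alleles(func_class: str, rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    if func_class in ("frameshift_del", "nonframeshift_del"):
        # deletions left-anchored with one reference base
        tail = "".join(_BASES[rng.integers(4)] for _ in range(2))
        return ref + tail, ref
    if func_class in ("frameshift_ins", "nonframeshift_ins"):
        return ref, ref + _BASES[rng.integers(4)]
    alt = _BASES[(rng.integers(1, 4) + _BASES.index(ref)) % 4]
    return ref, alt


def generate_callset(plan: CallsetPlan) -> Callset:
    """Generate a VCF 4.2 call set, annotation table and ground truth.

    Planted variants carry annotations consistent with surviving the
    prioritization cascade (exonic, high-priority class or damaging
    predictions, carriers exclusive to one group); each decoy violates
    exactly one named filter.  ``truth`` flags the variants expected in the
    tiered risk reports (tier-3 risk-increasing additionally subject to the
    >10-carrier / >=40% frequency rule).
    """
    plan.validate()
    rng = np.random.default_rng(plan.seed)
    width = len(str(max(plan.n_hldl, plan.n_lldl)))
    hldl_ids = [f"H{i + 1:0{width}d}" for i in range(plan.n_hldl)]
    lldl_ids = [f"L{i + 1:0{width}d}" for i in range(plan.n_lldl)]
    sample_groups = {**{s: "HLDL" for s in hldl_ids}, **{s: "LLDL" for s in lldl_ids}}

    planted_classes = ["frameshift_del", "stopgain_snv", "nonsynonymous_snv"]
    rows = []
    pos_by_chrom: dict[str, int] = {}

    def next_pos(chrom: str) -> int:
        pos_by_chrom[chrom] = pos_by_chrom.get(chrom, 10_000) + int(rng.integers(500, 5_000))
        return pos_by_chrom[chrom]

    def add_variant(gene: str, func_class: str, n_h: int, n_l: int, kind: str,
                    tier: int | None, known: bool) -> None:
        chrom = _GENE_CHROM[gene]
        pos = next_pos(chrom)
        ref, alt = _alleles(func_class, rng)
        if func_class == "nonsynonymous_snv":
            sift, polyphen = ("T", "B") if kind == "tolerated" else ("D", "D")
        elif func_class == "synonymous_snv" or func_class == "non_exonic":
            sift, polyphen = ".", "."
        else:
            sift, polyphen = ".", "."  # predictors undefined for fs/stop
        carriers_h = sorted(rng.choice(hldl_ids, size=n_h, replace=False))
        carriers_l = sorted(rng.choice(lldl_ids, size=n_l, replace=False))
        rsid = f"rs{int(rng.integers(10**6, 10**8))}" if known else "."
        rows.append(
            {
                "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                "gene": gene,
                "transcript": f"NM_{int(rng.integers(10**5, 10**6))}.1",
                "hgvs_c": f"c.{int(rng.integers(1, 5000))}{ref}>{alt}",
                "hgvs_p": ".",
                "func_raw": _RAW_FUNC[func_class],
                "func_class": func_class,
                "snp138": rsid,
                "kg2012apr_all": f"{rng.uniform(0.001, 0.05):.4f}" if known else ".",
                "esp6500_all": ".",
                "sift": sift, "polyphen": polyphen,
                "mutation_taster": "D" if kind == "planted" else ".",
                "fathmm": "D" if kind == "planted" else ".",
                "clinvar": "." ,
                "kind": kind, "tier": tier,
                "carriers_hldl": carriers_h, "carriers_lldl": carriers_l,
            }
        )

    for p in plan.planted:
        genes = _TIER_GENES[p.tier]
        for i in range(p.n_variants):
            gene = genes[int(rng.integers(len(genes)))]
            func_class = planted_classes[i % len(planted_classes)]
            known = i % 3 == 2  # mix of novel and database-known variants
            n_h = p.carriers if p.direction == "risk_increasing" else 0
            n_l = p.carriers if p.direction == "risk_reducing" else 0
            add_variant(gene, func_class, n_h, n_l, "planted", p.tier, known)

    all_genes = _TIER_GENES[1] + _TIER_GENES[2] + _TIER_GENES[3]
    for kind, count in plan.decoys.items():
        for _ in range(count):
            gene = all_genes[int(rng.integers(len(all_genes)))]
            if kind == "synonymous":
                add_variant(gene, "synonymous_snv", int(rng.integers(1, 6)), 0,
                            kind, None, True)
            elif kind == "tolerated":
                add_variant(gene, "nonsynonymous_snv", int(rng.integers(1, 6)), 0,
                            kind, None, True)
            elif kind == "shared":
                add_variant(gene, "nonsynonymous_snv", int(rng.integers(1, 6)),
                            int(rng.integers(1, 6)), kind, None, True)
            elif kind == "intronic":
                add_variant(gene, "non_exonic", int(rng.integers(1, 6)), 0,
                            kind, None, True)

    table = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "gene", "transcript", "hgvs_c",
                 "hgvs_p", "func_raw", "func_class", "snp138", "kg2012apr_all",
                 "esp6500_all", "sift", "polyphen", "mutation_taster", "fathmm",
                 "clinvar", "kind", "tier", "carriers_hldl", "carriers_lldl"],
    )
    if not table.empty:
        table = table.sort_values(
            ["chrom", "pos"], key=lambda s: s.map(_chrom_key) if s.name == "chrom" else s
        ).reset_index(drop=True)

    # ground truth: expected tiered-report membership, by construction
    survivors = []
    for row in table.itertuples():
        if row.kind != "planted":
            survivors.append(False)
            continue
        n_h, n_l = len(row.carriers_hldl), len(row.carriers_lldl)
        if row.tier == 3 and n_h > 0:
            survivors.append(n_l == 0 and n_h > 10 and n_h / plan.n_hldl >= 0.40)
        else:
            survivors.append(True)
    truth = table[["chrom", "pos", "ref", "alt", "gene", "kind", "tier"]].copy()
    truth["n_hldl"] = table["carriers_hldl"].map(len)
    truth["n_lldl"] = table["carriers_lldl"].map(len)
    truth["expected_survivor"] = survivors

    vcf_text = _render_vcf(table, hldl_ids + lldl_ids, plan.seed)
    annotation = table.drop(
        columns=["func_class", "kind", "tier", "carriers_hldl", "carriers_lldl"]
    ).rename(columns={"func_raw": "func"})
    return Callset(vcf_text, annotation, truth, sample_groups)


def _chrom_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def _render_vcf(table: pd.DataFrame, samples: list[str], seed: int) -> str:
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write(f"##source=fhpanel_synthetic(seed={seed})\n")
    for chrom in sorted({str(c) for c in table["chrom"]}, key=_chrom_key):
        buf.write(f"##contig=<ID={chrom}>\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
    buf.write("\t".join(samples) + "\n")
    for row in table.itertuples():
        carriers = set(row.carriers_hldl) | set(row.carriers_lldl)
        gts = ["0/1" if s in carriers else "0/0" for s in samples]
        rsid = row.snp138 if row.snp138 != "." else "."
        buf.write(
            f"{row.chrom}\t{row.pos}\t{rsid}\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t"
            + "\t".join(gts) + "\n"
        )
    return buf.getvalue()


def write_callset(
    callset: Callset, vcf_path, annotation_path, truth_path=None
) -> None:
    """Write the VCF, annotation TSV and (optionally) ground-truth TSV."""
    with open(vcf_path, "w") as fh:
        fh.write(callset.vcf_text)
    callset.annotation.to_csv(annotation_path, sep="\t", index=False)
    if truth_path is not None:
        callset.truth.to_csv(truth_path, sep="\t", index=False)
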