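"""Variant data model: VCF + annotation join, predictor harmonization, FH gene tiers.

A call set is a VCF 4.2 file (genotype calls per sample) joined to an
ANNOVAR-style annotation table keyed by ``(chrom, pos, ref, alt)``.  The
join yields :class:`AnnotatedVariant` records carrying the functional
class, in-silico predictor calls, database presence and the carrier sets
split by cohort group (a carrier is any sample with a non-reference
genotype call at the site; dosage is not modelled in discovery).

FH genes are organised in three tiers: tier 1 genes are directly causal
for familial hypercholesterolemia (LDLR, APOB, PCSK9, LDLRAP1), tier 2
genes regulate LDL or the expression of LDL-regulating genes, and tier 3
genes are otherwise implicated in lipid metabolism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd
from cyvcf2 import VCF

FUNC_CLASSES = (
    "synonymous_snv", "nonsynonymous_snv", "stopgain_snv", "stoploss_snv",
    "frameshift_del", "frameshift_ins", "nonframeshift_sub",
    "nonframeshift_del", "nonframeshift_ins", "non_exonic",
)

#: raw annotation strings -> internal functional classes (case-insensitive)
_FUNC_LOOKUP = {
    "nonsynonymous snv": "nonsynonymous_snv",
    "nonsynonymous_snv": "nonsynonymous_snv",
    "synonymous snv": "synonymous_snv",
    "synonymous_snv": "synonymous_snv",
    "stopgain": "stopgain_snv",
    "stopgain snv": "stopgain_snv",
    "stopgain_snv": "stopgain_snv",
    "stoploss": "stoploss_snv",
    "stoploss snv": "stoploss_snv",
    "stoploss_snv": "stoploss_snv",
    "frameshift deletion": "frameshift_del",
    "frameshift_del": "frameshift_del",
    "frameshift insertion": "frameshift_ins",
    "frameshift_ins": "frameshift_ins",
    "nonframeshift substitution": "nonframeshift_sub",
    "nonframeshift_sub": "nonframeshift_sub",
    "nonframeshift deletion": "nonframeshift_del",
    "nonframeshift_del": "nonframeshift_del",
    "nonframeshift insertion": "nonframeshift_ins",
    "nonframeshift_ins": "nonframeshift_ins",
    "intronic": "non_exonic",
    "intergenic": "non_exonic",
    "utr3": "non_exonic",
    "utr5": "non_exonic",
    "ncrna_intronic": "non_exonic",
    "ncrna_exonic": "non_exonic",
    "splicing": "non_exonic",
    "upstream": "non_exonic",
    "downstream": "non_exonic",
    "non_exonic": "non_exonic",
}

# predictor harmonization: unknown raw strings map to "missing", never to a
# damaging call
_SIFT_LOOKUP = {"d": "damaging", "damaging": "damaging",
                "t": "tolerated", "tolerated": "tolerated"}
_POLYPHEN_LOOKUP = {
    "d": "probably_damaging", "probably damaging": "probably_damaging",
    "probably_damaging": "probably_damaging",
    "p": "possibly_damaging", "possibly damaging": "possibly_damaging",
    "possibly_damaging": "possibly_damaging",
    "b": "benign", "benign": "benign",
}
_MT_LOOKUP = {"a": "disease_causing", "d": "disease_causing",
              "disease_causing": "disease_causing",
              "n": "polymorphism", "p": "polymorphism",
              "polymorphism": "polymorphism"}
_FATHMM_LOOKUP = {"d": "damaging", "damaging": "damaging",
                  "t": "tolerated", "tolerated": "tolerated"}

_MISSING_TOKENS = {"", ".", "na", "nan", "none", "-"}


def _harmonize(raw, lookup: dict[str, str]) -> str:
    key = str(raw).strip().lower()
    if key in _MISSING_TOKENS:
        return "missing"
    return lookup.get(key, "missing")


def harmonize_func_class(raw) -> str:
    """Map a raw ANNOVAR-style functional annotation to the internal enumeration."""
    key = str(raw).strip().lower().replace(";", ",").split(",")[0]
    if key in _MISSING_TOKENS:
        return "non_exonic"
    try:
        return _FUNC_LOOKUP[key]
    except KeyError:
        raise ValueError(f"unrecognized functional class {raw!r}") from None


@dataclass
class AnnotatedVariant:
    """One joined variant allele with annotations and per-group carrier sets."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    gene: str
    transcript: str = ""
    hgvs_c: str = ""  # carried as opaque annotation, never parsed
    hgvs_p: str = ""
    func_class: str = "non_exonic"
    dbsnp_id: str | None = None
    known_in_databases: bool = False
    sift: str = "missing"
    polyphen: str = "missing"
    mutation_taster: str = "missing"
    fathmm: str = "missing"
    clinvar: str = "missing"
    carriers_hldl: frozenset[str] = frozenset()
    carriers_lldl: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.func_class not in FUNC_CLASSES:
            raise ValueError(f"unknown func_class {self.func_class!r}")
        overlap = set(self.carriers_hldl) & set(self.carriers_lldl)
        if overlap:
            raise ValueError(f"samples in both carrier sets: {sorted(overlap)}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def n_hldl(self) -> int:
        return len(self.carriers_hldl)

    @property
    def n_lldl(self) -> int:
        return len(self.carriers_lldl)

    @property
    def novel(self) -> bool:
        """No dbSNP id and absent from the population databases."""
        return self.dbsnp_id is None and not self.known_in_databases


@dataclass(frozen=True)
class TierConfig:
    """FH gene panel tiers; sets must be pairwise disjoint.

    ``tier3_genes`` may be the sentinel string ``"complement"``, in which
    case any gene of ``universe`` not already in tiers 1-2 is tier 3.
    """

    tier1_genes: frozenset[str] = frozenset({"LDLR", "APOB", "PCSK9", "LDLRAP1"})
    tier2_genes: frozenset[str] = frozenset(
        {"NYNRIN", "CELSR2", "PARP10", "MAF1", "OSBPL7",
         "DCPS", "GPAA1", "LPA", "OPLAH", "SPATC1"}
    )
    tier3_genes: frozenset[str] | str = frozenset(
        {"WDR74", "FRG1BP", "SEC13", "KEAP1", "GLMP", "MUC12", "UBR1",
         "GBP7", "RNF212", "DPCR1", "HEATR5A", "TIMELESS", "GTF3C1"}
    )
    universe: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        t3 = self.tier3_genes if isinstance(self.tier3_genes, frozenset) else frozenset()
        if isinstance(self.tier3_genes, str) and self.tier3_genes != "complement":
            raise ValueError(
                f"tier3_genes must be a set or 'complement', got {self.tier3_genes!r}"
            )
        for a, b, name in (
            (self.tier1_genes, self.tier2_genes, "tier1/tier2"),
            (self.tier1_genes, t3, "tier1/tier3"),
            (self.tier2_genes, t3, "tier2/tier3"),
        ):
            if a & b:
                raise ValueError(f"{name} gene sets overlap: {sorted(a & b)}")


def assign_tier(variant: AnnotatedVariant | str, config: TierConfig | None = None) -> int | None:
    """Tier (1, 2, 3) of a variant's gene, or ``None`` if outside the panels."""
    config = config or TierConfig()
    gene = variant if isinstance(variant, str) else variant.gene
    if not gene:
        raise ValueError("empty gene symbol")
    if gene in config.tier1_genes:
        return 1
    if gene in config.tier2_genes:
        return 2
    if config.tier3_genes == "complement":
        return 3 if gene in config.universe else None
    return 3 if gene in config.tier3_genes else None


def _truthy_db(value) -> bool:
    return str(value).strip().lower() not in _MISSING_TOKENS | {"0", "0.0", "false"}


def read_callset(
    vcf_path, annotation_path, sample_groups: dict[str, str]
) -> tuple[list[AnnotatedVariant], pd.DataFrame]:
    """Join a VCF to its annotation table.

    Returns ``(variants, orphans)``: one :class:`AnnotatedVariant` per
    joined ALT allele (multi-allelic sites are split), and the annotation
    rows with no matching VCF allele as an orphan report.  Raises on
    duplicate annotation keys or on VCF samples absent from
    ``sample_groups``.
    """
    ann = pd.read_csv(
        annotation_path, sep="\t", dtype={"chrom": str}, keep_default_na=False
    )
    key_cols = ["chrom", "pos", "ref", "alt"]
    missing_cols = [c for c in key_cols + ["gene", "func"] if c not in ann.columns]
    if missing_cols:
        raise ValueError(f"annotation table missing columns: {missing_cols}")
    keys = list(zip(ann["chrom"], ann["pos"].astype(int), ann["ref"], ann["alt"]))
    dupes = pd.Series(keys).duplicated()
    if dupes.any():
        raise ValueError(f"duplicate annotation keys: {sorted(set(k for k, d in zip(keys, dupes) if d))}")
    ann_by_key = {k: row for k, (_, row) in zip(keys, ann.iterrows())}

    vcf = VCF(str(vcf_path))
    unknown = [s for s in vcf.samples if s not in sample_groups]
    if unknown:
        raise ValueError(f"VCF samples absent from group map: {unknown}")
    samples = list(vcf.samples)

    variants: list[AnnotatedVariant] = []
    matched: set[tuple] = set()
    for record in vcf:
        genotypes = record.genotypes  # [allele_a, allele_b, phased] per sample
        for alt_index, alt in enumerate(record.ALT, start=1):
            key = (str(record.CHROM), int(record.POS), record.REF, alt)
            row = ann_by_key.get(key)
            if row is None:
                continue
            matched.add(key)
            carriers = {
                s for s, gt in zip(samples, genotypes)
                if alt_index in gt[:-1]
            }
            rsid = str(row.get("snp138", ".")).strip()
            dbsnp_id = None if rsid in _MISSING_TOKENS else rsid
            in_dbs = (
                dbsnp_id is not None
                or _truthy_db(row.get("kg2012apr_all", "."))
                or _truthy_db(row.get("esp6500_all", "."))
            )
            variants.append(
                AnnotatedVariant(
                    chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
                    gene=str(row["gene"]),
                    transcript=str(row.get("transcript", "")),
                    hgvs_c=str(row.get("hgvs_c", "")),
                    hgvs_p=str(row.get("hgvs_p", "")),
                    func_class=harmonize_func_class(row["func"]),
                    dbsnp_id=dbsnp_id,
                    known_in_databases=in_dbs,
                    sift=_harmonize(row.get("sift", "."), _SIFT_LOOKUP),
                    polyphen=_harmonize(row.get("polyphen", "."), _POLYPHEN_LOOKUP),
                    mutation_taster=_harmonize(row.get("mutation_taster", "."), _MT_LOOKUP),
                    fathmm=_harmonize(row.get("fathmm", "."), _FATHMM_LOOKUP),
                    clinvar=(
                        "missing"
                        if str(row.get("clinvar", ".")).strip().lower() in _MISSING_TOKENS
                        else str(row.get("clinvar"))
                    ),
                    carriers_hldl=frozenset(
                        s for s in carriers if sample_groups[s] == "HLDL"
                    ),
                    carriers_lldl=frozenset(
                        s for s in carriers if sample_groups[s] == "LLDL"
                    ),
                )
            )
    orphan_mask = [k not in matched for k in keys]
    orphans = ann[orphan_mask].reset_index(drop=True)
    return variants, orphans
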