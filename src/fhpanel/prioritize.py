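"""The exome-variant prioritization cascade.

Discovery-phase triage of annotated variants into tiered risk-increasing
and risk-reducing candidate lists:

1. keep exonic variants only;
2. drop synonymous SNVs;
3. drop variants predicted tolerable by *both* SIFT and PolyPhen-2
   (frameshift / stop-gain / stop-loss bypass this filter — the predictors
   are undefined for them; a missing prediction never causes removal);
4. classify direction by carrier exclusivity: carried only by cases =>
   risk-increasing, only by controls => risk-reducing, both or neither =>
   none;
5. rank by (gene tier, functional-class priority, carrier count);
6. tier-3 risk-increasing candidates must additionally be high-frequency
   (> ``min_carriers`` case carriers and >= ``min_fraction`` of the case
   arm, with zero control carriers).

MutationTaster / FATHMM / ClinVar calls are carried into the reports for
impact assessment of the shortlisted variants; they are not filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .variants import AnnotatedVariant, TierConfig, assign_tier

HIGH_PRIORITY_CLASSES = frozenset({"frameshift_del", "frameshift_ins",
                                   "stopgain_snv", "stoploss_snv"})
NONFRAMESHIFT_CLASSES = frozenset({"nonframeshift_sub", "nonframeshift_del",
                                   "nonframeshift_ins"})


@dataclass
class TriageResult:
    """Cascade outcome for one variant."""

    variant: AnnotatedVariant
    passed_exonic: bool
    passed_nonsynonymous_filter: bool
    passed_deleteriousness: bool
    class_priority: int | None  # 1 fs/stop, 2 nonsyn SNV, 3 nonframeshift
    tier: int | None
    direction: str  # risk_increasing | risk_reducing | none
    n_hldl: int
    n_lldl: int
    novel: bool


def class_priority(variant: AnnotatedVariant) -> int | None:
    """Functional-class priority for exonic non-synonymous survivors."""
    if variant.func_class in HIGH_PRIORITY_CLASSES:
        return 1
    if variant.func_class == "nonsynonymous_snv":
        return 2
    if variant.func_class in NONFRAMESHIFT_CLASSES:
        return 3
    return None


def filter_exonic(variants: list[AnnotatedVariant]) -> list[AnnotatedVariant]:
    """Keep exonic variants only."""
    return [v for v in variants if v.func_class != "non_exonic"]


def filter_synonymous(variants: list[AnnotatedVariant]) -> list[AnnotatedVariant]:
    """Drop synonymous SNVs."""
    return [v for v in variants if v.func_class != "synonymous_snv"]


def filter_tolerable(variants: list[AnnotatedVariant]) -> list[AnnotatedVariant]:
    """Drop variants called tolerated by SIFT *and* benign by PolyPhen-2.

    Frameshift / stop-gain / stop-loss variants bypass the filter; missing
    predictions never cause removal.
    """
    out = []
    for v in variants:
        if v.func_class in HIGH_PRIORITY_CLASSES:
            out.append(v)
        elif v.sift == "tolerated" and v.polyphen == "benign":
            continue
        else:
            out.append(v)
    return out


def classify_direction(variant: AnnotatedVariant) -> str:
    """Carrier-exclusivity direction call."""
    if variant.n_hldl >= 1 and variant.n_lldl == 0:
        return "risk_increasing"
    if variant.n_lldl >= 1 and variant.n_hldl == 0:
        return "risk_reducing"
    return "none"


def rank_class_priority(
    results: list[TriageResult],
) -> list[TriageResult]:
    """Stable sort by (tier, class priority, carriers descending, locus).

    Variants outside the configured panels (tier ``None``) sort last.
    """
    def sort_key(item: tuple[int, TriageResult]):
        i, r = item
        return (
            r.tier if r.tier is not None else 99,
            r.class_priority if r.class_priority is not None else 99,
            -(r.n_hldl + r.n_lldl),
            r.variant.chrom,
            r.variant.pos,
            i,  # stability
        )

    return [r for _, r in sorted(enumerate(results), key=sort_key)]


def filter_tier3_high_frequency(
    results: list[TriageResult],
    n_group: int,
    min_carriers: int = 10,
    min_fraction: float = 0.40,
) -> list[TriageResult]:
    """High-frequency rule for tier-3 risk-increasing candidates.

    A tier-3 risk-increasing variant is kept iff it has strictly more than
    ``min_carriers`` case carriers, at least ``min_fraction`` of the case
    arm, and no control carriers.  Other tiers/directions pass through.
    """
    if n_group <= 0:
        raise ValueError("case-group size must be positive")
    out = []
    for r in results:
        if r.tier == 3 and r.direction == "risk_increasing":
            if r.n_hldl > min_carriers and r.n_hldl / n_group >= min_fraction and r.n_lldl == 0:
                out.append(r)
        else:
            out.append(r)
    return out


def run_cascade(
    variants: list[AnnotatedVariant],
    config: TierConfig | None = None,
    n_hldl: int = 25,
    n_lldl: int = 25,
    min_carriers: int = 10,
    min_fraction: float = 0.40,
) -> tuple[list[TriageResult], dict]:
    """Run the full cascade; returns ranked survivors and a per-stage audit.

    Survivors are the directionally classified (risk-increasing or
    risk-reducing) variants that passed every filter, ranked by
    :func:`rank_class_priority`.  The audit log records input/removed/kept
    counts per stage so counts reconcile exactly.
    """
    config = config or TierConfig()
    audit: dict = {"input": len(variants), "stages": []}

    def log(stage: str, before: int, after: int) -> None:
        audit["stages"].append(
            {"stage": stage, "in": before, "removed": before - after, "out": after}
        )

    stage1 = filter_exonic(variants)
    log("exonic", len(variants), len(stage1))
    stage2 = filter_synonymous(stage1)
    log("synonymous", len(stage1), len(stage2))
    stage3 = filter_tolerable(stage2)
    log("tolerable", len(stage2), len(stage3))

    results = []
    for v in stage3:
        direction = classify_direction(v)
        results.append(
            TriageResult(
                variant=v,
                passed_exonic=True,
                passed_nonsynonymous_filter=True,
                passed_deleteriousness=True,
                class_priority=class_priority(v),
                tier=assign_tier(v, config),
                direction=direction,
                n_hldl=v.n_hldl,
                n_lldl=v.n_lldl,
                novel=v.novel,
            )
        )
    directional = [r for r in results if r.direction != "none"]
    log("exclusivity", len(results), len(directional))
    in_panel = [r for r in directional if r.tier is not None]
    log("tier_panel", len(directional), len(in_panel))
    survivors = filter_tier3_high_frequency(
        in_panel, n_hldl, min_carriers=min_carriers, min_fraction=min_fraction
    )
    log("tier3_frequency", len(in_panel), len(survivors))
    audit["survivors"] = len(survivors)
    return rank_class_priority(survivors), audit


_REPORT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "nomenclature", "variant_type",
    "dbsnp_id", "clinvar", "novel", "direction", "n_hldl", "n_lldl",
]


def build_reports(results: list[TriageResult]) -> dict[int, pd.DataFrame]:
    """Per-tier report tables (the shape of the published tier tables).

    Keys are tiers 1-3; every key is present even when a tier is empty.
    Rows keep the :func:`rank_class_priority` ordering, so frameshift and
    stop variants lead each tier.
    """
    ranked = rank_class_priority(results)
    reports: dict[int, pd.DataFrame] = {}
    for tier in (1, 2, 3):
        rows = []
        for r in ranked:
            if r.tier != tier:
                continue
            v = r.variant
            nomenclature = ":".join(
                part for part in (v.transcript, v.hgvs_c, v.hgvs_p)
                if part and part != "."
            )
            rows.append(
                {
                    "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                    "gene": v.gene, "nomenclature": nomenclature,
                    "variant_type": v.func_class,
                    "dbsnp_id": v.dbsnp_id or "",
                    "clinvar": "" if v.clinvar == "missing" else v.clinvar,
                    "novel": r.novel,
                    "direction": r.direction,
                    "n_hldl": r.n_hldl, "n_lldl": r.n_lldl,
                }
            )
        reports[tier] = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    return reports


def select_validation_panel(
    risk_increasing: list[TriageResult],
    risk_reducing: list[TriageResult],
    n_increasing: int = 27,
    n_reducing: int = 18,
) -> list[TriageResult]:
    """Deterministic top-k panel for genotyping validation.

    Takes the first ``n_increasing`` risk-increasing and ``n_reducing``
    risk-reducing candidates in :func:`rank_class_priority` order (ties
    broken by the documented chain: tier, class priority, carrier count,
    locus, input order).
    """
    for name, pool, n in (
        ("risk-increasing", risk_increasing, n_increasing),
        ("risk-reducing", risk_reducing, n_reducing),
    ):
        if n > len(pool):
            raise ValueError(
                f"requested {n} {name} variants but only {len(pool)} available"
            )
    return rank_class_priority(risk_increasing)[:n_increasing] + rank_class_priority(
        risk_reducing
    )[:n_reducing]
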