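import numpy as np
import pytest

from fhpanel import synthetic


@pytest.fixture(scope="session")
def exact_cohort():
    """Validation cohort reproducing every printed 2x2 cell exactly."""
    return synthetic.generate_cohort(synthetic.table1_cohort_spec("exact", seed=11))


@pytest.fixture(scope="session")
def demo_callset():
    """A discovery-style call set with every decoy kind and a tier-3 boundary."""
    plan = synthetic.CallsetPlan(
        planted=(
            synthetic.PlantSpec(1, "risk_increasing", 5, 2),
            synthetic.PlantSpec(2, "risk_increasing", 4, 6),
            synthetic.PlantSpec(3, "risk_increasing", 3, 15),
            synthetic.PlantSpec(3, "risk_increasing", 2, 8),  # fails frequency rule
            synthetic.PlantSpec(2, "risk_reducing", 3, 4),
        ),
        decoys={"synonymous": 3, "tolerated": 2, "shared": 2, "intronic": 2},
        seed=2024,
    )
    return plan, synthetic.generate_callset(plan)


@pytest.fixture()
def demo_callset_files(tmp_path, demo_callset):
    _, callset = demo_callset
    vcf, ann = tmp_path / "callset.vcf", tmp_path / "annotation.tsv"
    synthetic.write_callset(callset, vcf, ann)
    return vcf, ann, callset


def random_callset_plan(rng: np.random.Generator, seed: int) -> synthetic.CallsetPlan:
    """A randomized plan exercising all tiers, directions and decoy kinds."""
    plants = []
    for _ in range(int(rng.integers(0, 5))):
        tier = int(rng.integers(1, 4))
        direction = ["risk_increasing", "risk_reducing"][int(rng.integers(2))]
        plants.append(
            synthetic.PlantSpec(
                tier, direction, int(rng.integers(1, 8)), int(rng.integers(1, 26))
            )
        )
    decoys = {k: int(rng.integers(0, 4)) for k in synthetic.DECOY_KINDS}
    return synthetic.CallsetPlan(planted=tuple(plants), decoys=decoys, seed=seed)


# gene tiers restated from the published panels, independent of TierConfig
ORACLE_TIER1 = {"LDLR", "APOB", "PCSK9", "LDLRAP1"}
ORACLE_TIER2 = {"NYNRIN", "CELSR2", "PARP10", "MAF1", "OSBPL7",
                "DCPS", "GPAA1", "LPA", "OPLAH", "SPATC1"}
ORACLE_TIER3 = {"WDR74", "FRG1BP", "SEC13", "KEAP1", "GLMP", "MUC12", "UBR1",
                "GBP7", "RNF212", "DPCR1", "HEATR5A", "TIMELESS", "GTF3C1"}

_HIGH_PRIORITY = {"frameshift_del", "frameshift_ins", "stopgain_snv", "stoploss_snv"}


def brute_force_survivors(variants, n_hldl=25, n_lldl=25) -> set:
    """Independent re-statement of the cascade predicates, applied directly."""
    keys = set()
    for v in variants:
        if v.func_class == "non_exonic":
            continue
        if v.func_class == "synonymous_snv":
            continue
        if (
            v.func_class not in _HIGH_PRIORITY
            and v.sift == "tolerated"
            and v.polyphen == "benign"
        ):
            continue
        nh, nl = len(v.carriers_hldl), len(v.carriers_lldl)
        if nh >= 1 and nl == 0:
            direction = "risk_increasing"
        elif nl >= 1 and nh == 0:
            direction = "risk_reducing"
        else:
            continue
        if v.gene in ORACLE_TIER1:
            tier = 1
        elif v.gene in ORACLE_TIER2:
            tier = 2
        elif v.gene in ORACLE_TIER3:
            tier = 3
        else:
            continue
        if tier == 3 and direction == "risk_increasing":
            if not (nh > 10 and nh / n_hldl >= 0.40 and nl == 0):
                continue
        keys.add((v.chrom, v.pos, v.ref, v.alt))
    return keys
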