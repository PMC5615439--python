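"""Energy-expenditure partitioning.

Total energy expenditure (TEE) splits into resting metabolic rate (RMR),
diet-induced thermogenesis (DIT, taken as a fixed 10% of TEE) and physical
activity energy expenditure (PAEE = TEE - RMR - DIT).  Physical activity
level (PAL) is the dimensionless ratio TEE/RMR.  The partition is exact by
construction: rmr + dit + paee == tee.

On a low-expenditure day a measured RMR can exceed 0.9 x TEE; the derived
PAEE is then negative.  That is flagged (``paee_negative``) but retained —
downstream log-transforms handle it via their offset policy.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError

#: Fraction of TEE attributed to diet-induced thermogenesis.
DEFAULT_DIT_FRACTION = 0.10


@dataclass(frozen=True)
class EnergyPartition:
    tee: float
    rmr: float
    dit: float
    paee: float
    pal: float
    paee_negative: bool = False


def derive_components(
    tee: float, rmr: float, dit_fraction: float = DEFAULT_DIT_FRACTION
) -> EnergyPartition:
    """Partition a daily TEE given the subject's measured RMR.

    >>> p = derive_components(2103.0, 1481.0)
    >>> round(p.dit, 1), round(p.paee, 1), round(p.pal, 3)
    (210.3, 411.7, 1.42)
    """
    if tee <= 0 or rmr <= 0:
        raise DomainError(f"tee and rmr must be positive (tee={tee}, rmr={rmr})")
    if not 0 <= dit_fraction < 1:
        raise DomainError(f"dit_fraction must be in [0, 1), got {dit_fraction}")
    dit = dit_fraction * tee
    paee = tee - rmr - dit
    return EnergyPartition(
        tee=tee, rmr=rmr, dit=dit, paee=paee, pal=tee / rmr, paee_negative=paee < 0
    )


def component_shares(partition: EnergyPartition) -> tuple[float, float, float]:
    """Percent of TEE contributed by (rmr, dit, paee); sums to 100 exactly."""
    tee = partition.tee
    rmr_pct = 100.0 * partition.rmr / tee
    dit_pct = 100.0 * partition.dit / tee
    return (rmr_pct, dit_pct, 100.0 - rmr_pct - dit_pct)
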