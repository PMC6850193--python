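"""Hardy-Weinberg / penetrance bounds that motivate the MAF filters.

If a single variant fully explained a trait of population frequency t with
penetrance f, Hardy-Weinberg equilibrium bounds its allele frequency q:
recessive, f * q^2 = t, so q = sqrt(t / f); dominant, f * (2q(1-q) + q^2) =
t, solved exactly for q.  For a 1% trait these give q = 0.10 at full
penetrance (recessive) and q = 0.14 at 50% penetrance — the reasoning
behind the 10% recessive and 1% dominant MAF cutoffs, which are therefore
inclusive rather than strict filters (allelic heterogeneity only lowers the
per-variant bound).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

from .cohort import ValidationError


@dataclass(frozen=True)
class PenetranceModel:
    """A single-variant explanation of a trait.

    ``penetrance`` is the probability that a qualifying genotype (homozygote
    under the recessive model, carrier under the dominant model) expresses
    the trait; 50% models left-right randomization as seen in visceral
    situs genetics.
    """

    trait_frequency: float
    penetrance: float
    inheritance: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.trait_frequency <= 1.0:
            raise ValidationError("trait_frequency outside [0, 1]")
        if not 0.0 < self.penetrance <= 1.0:
            raise ValidationError("penetrance outside (0, 1]")
        if self.inheritance not in ("recessive", "dominant"):
            raise ValidationError(f"unknown inheritance {self.inheritance!r}")
        if self.trait_frequency > self.penetrance:
            raise ValidationError(
                "trait_frequency exceeds penetrance: no allele frequency "
                "can explain the trait with a single variant"
            )


def max_allele_freq(model: PenetranceModel) -> float:
    """Largest allele frequency consistent with the model under HWE.

    The dominant case solves f*(2q(1-q) + q^2) = t exactly (taking the root
    in [0, 1]) rather than using the 2q approximation.
    """
    t, f = model.trait_frequency, model.penetrance
    if model.inheritance == "recessive":
        return sqrt(t / f)
    # dominant: f*(2q - q^2) = t  =>  q^2 - 2q + t/f = 0
    return 1.0 - sqrt(1.0 - t / f)


def genotype_freq(q: float, genotype: str) -> float:
    """Hardy-Weinberg genotype frequency: q^2 (hom_alt) or 2q(1-q) (het)."""
    if not 0.0 <= q <= 1.0:
        raise ValidationError("allele frequency outside [0, 1]")
    if genotype == "hom_alt":
        return q * q
    if genotype == "het":
        return 2.0 * q * (1.0 - q)
    raise ValidationError(f"unknown genotype {genotype!r}")
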