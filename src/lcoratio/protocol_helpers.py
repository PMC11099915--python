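"""Staining-protocol concentration arithmetic.

The double-staining solution is made by diluting each dye stock and
mixing the two working solutions by volume (2 parts qFTAA working
solution to 1 part hFTAA).  Only c1*V1 = c2*V2 arithmetic is done here;
molecular weights are never needed.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["StainRecipe", "final_concentration", "QFTAA_RECIPE", "HFTAA_RECIPE"]


@dataclass(frozen=True)
class StainRecipe:
    """One dye's path from stock to the final mixed staining solution."""

    stock_molarity_mm: float  # stock concentration, mM
    dilution_factor: float  # e.g. 10000 for a 1:10000 dilution
    mix_parts: int  # volume parts of this dye's working solution
    total_parts: int  # total volume parts of the mixture

    def __post_init__(self) -> None:
        if self.stock_molarity_mm <= 0:
            raise ValueError("stock molarity must be positive")
        if self.dilution_factor <= 0:
            raise ValueError("dilution factor must be positive")
        if self.mix_parts <= 0 or self.total_parts <= 0:
            raise ValueError("mix parts must be positive")
        if self.mix_parts > self.total_parts:
            raise ValueError("mix_parts cannot exceed total_parts")


def final_concentration(recipe: StainRecipe) -> float:
    """Final concentration (nM) of one dye in the mixed staining solution.

    stock[mM] * 1e6 / dilution * (mix_parts / total_parts).
    """
    return (
        recipe.stock_molarity_mm * 1e6 / recipe.dilution_factor
        * recipe.mix_parts / recipe.total_parts
    )


#: 1 mg/mL qFTAA stock in 2 mM NaOH = 1.8 mM, diluted 1:10000, 2 of 3
#: volume parts -> 120 nM in the final solution.
QFTAA_RECIPE = StainRecipe(stock_molarity_mm=1.8, dilution_factor=10000,
                           mix_parts=2, total_parts=3)

#: 1 mg/mL hFTAA stock = 1.1 mM, diluted 1:1392, 1 of 3 volume parts
#: -> 263.4 nM (protocol write-ups round this to 262 nM; the arithmetic
#: here is kept exact and the discrepancy documented, not corrected).
HFTAA_RECIPE = StainRecipe(stock_molarity_mm=1.1, dilution_factor=1392,
                           mix_parts=1, total_parts=3)
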