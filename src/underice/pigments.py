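"""Chlorophyll a by the monochromatic (Lorenzen) acidification method.

Absorbance of an ethanol extract is read at 665 nm before and after
acidification, each corrected for turbidity at 750 nm; the acid-labile part
of the 665 nm signal is chlorophyll a:

    chl a [µg L⁻¹] = 26.7 · [(A665ᵦ − A750ᵦ) − (A665ₐ − A750ₐ)] · v / (V · l)

with v the extract volume (mL), V the filtered water volume (L) and l the
cuvette path length (cm). Negative results (acidified signal exceeding the
fresh one, i.e. pure noise at low biomass) are clipped to 0 and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["ChlaRecord", "ChlaResult", "lorenzen_chla", "summarize_replicates"]

LORENZEN_CONSTANT = 26.7


@dataclass
class ChlaRecord:
    a665_before: float
    a750_before: float
    a665_after: float
    a750_after: float
    v_extract: float  # mL
    v_filtered: float  # L
    path_length: float = 1.0  # cm
    replicate_id: str = ""

    def __post_init__(self) -> None:
        for a in (self.a665_before, self.a750_before, self.a665_after, self.a750_after):
            if a < 0:
                raise ValueError("absorbances must be >= 0")
        if self.v_extract <= 0 or self.v_filtered <= 0 or self.path_length <= 0:
            raise ValueError("volumes and path length must be > 0")


@dataclass
class ChlaResult:
    chla: float  # µg L⁻¹, clipped at 0
    clipped: bool
    replicate_id: str = ""


def lorenzen_chla(rec: ChlaRecord) -> ChlaResult:
    """Chlorophyll a (µg L⁻¹) from one before/after acidification reading."""
    before = rec.a665_before - rec.a750_before
    after = rec.a665_after - rec.a750_after
    value = (
        LORENZEN_CONSTANT * (before - after) * rec.v_extract
        / (rec.v_filtered * rec.path_length)
    )
    if value < 0:
        return ChlaResult(chla=0.0, clipped=True, replicate_id=rec.replicate_id)
    return ChlaResult(chla=value, clipped=False, replicate_id=rec.replicate_id)


def summarize_replicates(results: Sequence[ChlaResult]) -> tuple[float, float]:
    """Mean and (ddof=1) SD of replicate chl-a determinations."""
    values = np.asarray([r.chla for r in results], dtype=float)
    if values.size == 0:
        raise ValueError("no replicates")
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return float(np.mean(values)), sd
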