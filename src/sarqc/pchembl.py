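"""pChEMBL: the negative log10 of a dose-response activity in molar units.

A Ki of 1 nM corresponds to a pChEMBL of 9. The value is computed only for
clean records: a dose-response standard type, an exact ('=') relation, a
positive value in nM and no data validity comment. The potential-duplicate
flag is *not* a data validity comment and does not suppress pChEMBL.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

from .config import CurationConfig


def compute_pchembl(
    standard_type: Optional[str],
    standard_relation: Optional[str],
    standard_value: Optional[float],
    standard_units: Optional[str],
    data_validity_comment: Optional[str],
    config: CurationConfig,
) -> Optional[float]:
    """-log10(value in M) = 9 - log10(value in nM), rounded to 2 decimals.

    Returns ``None`` for ineligible records (wrong type or units, censored
    or approximate relation, non-positive value, or any validity comment).
    """
    if (
        standard_type is None
        or standard_type not in config.pchembl_types
        or standard_units != "nM"
        or standard_relation != "="
        or standard_value is None
        or standard_value <= 0
        or data_validity_comment is not None
    ):
        return None
    value = 9.0 - math.log10(standard_value)
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
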