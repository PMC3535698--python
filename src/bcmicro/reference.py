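"""Published miR-124 Ago2-IP benchmark parameters.

Reporting rates for the six tools were estimated on a reference set of
miR-124 targets (luciferase-validated plus Ago2-IP enriched genes)
against the remaining genes as negatives; they are bundled here verbatim
so benchmark-parity runs do not need the external reference data.  The
genome-wide prior p(y=1) published alongside that benchmark is stored as
a constant: its exact source counts are not recoverable, so it is not
derived from arithmetic here.
"""

from __future__ import annotations

import csv
from importlib import resources

from .fusion import ReportingRates
from .score_io import TOOL_ORDER

#: Published genome-wide prior probability that a random (miRNA, gene)
#: pair is a true target, from the miR-124 Ago2-IP benchmark.
REFERENCE_PRIOR = 0.0133

_RATES_RESOURCE = "data/mir124_reference_rates.tsv"


def reference_rates() -> dict[str, ReportingRates]:
    """Load the bundled per-tool reporting rates, keyed by tool name."""
    rates: dict[str, ReportingRates] = {}
    path = resources.files("bcmicro").joinpath(_RATES_RESOURCE)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            rates[row["tool"]] = ReportingRates(
                tpr=float(row["tpr"]),
                fpr=float(row["fpr"]),
                tnr=float(row["tnr"]),
                fnr=float(row["fnr"]),
            )
    if set(rates) != set(TOOL_ORDER):
        raise RuntimeError("bundled rate table does not cover the six tools")
    return rates
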