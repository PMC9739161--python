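"""Published island-wide service totals for Hainan Island, 1980-2015.

Seven-epoch series of the four regulating-service totals as reported for
the real island (water retention in 1e9 m3, soil conservation in 1e9 t,
carbon sequestration and oxygen release in 1e6 t).  These are inputs to
the change-accounting arithmetic, not outputs of this package: the
pipeline's own totals come from the synthetic island and are on a toy
scale.
"""

from __future__ import annotations

from .services import ServiceStack, ingest_totals

REPORTED_YEARS = (1980, 1990, 1995, 2000, 2005, 2010, 2015)

#: island totals per epoch, in the unit conventional for each service
REPORTED_TOTALS = {
    "water_retention": (23.31, 23.34, 23.76, 23.34, 23.40, 23.39, 23.15),
    "soil_conservation": (2.90, 2.90, 2.93, 2.86, 2.84, 2.79, 2.79),
    "carbon_sequestration": (9.68, 9.69, 9.73, 9.63, 9.61, 9.47, 9.42),
    "oxygen_release": (56.05, 56.06, 56.16, 55.98, 55.92, 55.64, 55.53),
}


def reported_stack(service: str) -> ServiceStack:
    """The published totals series for one service, as a ServiceStack."""
    return ingest_totals(service, REPORTED_YEARS, REPORTED_TOTALS[service])


def reported_changes() -> dict[str, float]:
    """First-to-last change of each published series, rounded to the printed precision."""
    return {s: round(reported_stack(s).change, 2) for s in REPORTED_TOTALS}
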