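"""The first-trimester marker panel and its CSV column mapping.

Four maternal-serum / ultrasound markers are screened at 11-13+6 weeks:

* PAPP-A       -- pregnancy-associated plasma protein A (decreased in T21)
* free beta-hCG -- free beta subunit of hCG (increased in T21)
* NT           -- nuchal translucency thickness (increased in T21)
* AFP-L2       -- lens-culinaris-agglutinin weakly-binding AFP variant
                  (increased in T21)

All marker values in this package are on the MoM (multiple of the median)
scale unless a column name says otherwise.
"""

from __future__ import annotations

PAPP_A = "PAPP-A"
FREE_BHCG = "free beta-hCG"
NT = "NT"
AFP_L2 = "AFP-L2"

#: Canonical marker panel, in reporting order.
PANEL: tuple[str, ...] = (PAPP_A, FREE_BHCG, NT, AFP_L2)

#: Marker name -> CSV column stem (the MoM column is ``<stem>_mom``).
COLUMN_STEMS: dict[str, str] = {
    PAPP_A: "papp_a",
    FREE_BHCG: "free_bhcg",
    NT: "nt",
    AFP_L2: "afp_l2",
}

#: Labels used in the ``group`` column of cohort files.
AFFECTED_LABEL = "trisomy21"
CONTROL_LABEL = "control"


def mom_column(marker: str) -> str:
    """CSV column name holding the MoM value of *marker*."""
    return COLUMN_STEMS[marker] + "_mom"


def raw_column(marker: str) -> str:
    """CSV column name holding the pseudo-raw concentration of *marker*."""
    return COLUMN_STEMS[marker] + "_raw"


def adjusted_column(marker: str) -> str:
    """CSV column name holding the GA/weight-adjusted MoM of *marker*."""
    return COLUMN_STEMS[marker] + "_adj_mom"
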