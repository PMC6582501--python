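"""Packaged data tables.

``table2_ctc_counts.tsv`` transcribes the study's 20-patient two-method
CTC enumeration table (10 NSCLC, 10 SCLC; patient ids 001–021 with 005
and 009 reassigned to the SCLC arm as printed and 017 never sampled).
Two typeset rows concatenate the two methods' counts; the fixture adopts
the splits 014 = (12, 111) and 021 = (22, 16), consistent with the
printed per-method ranges (1–4007 unicapture, 1–3810 quadcapture).  Every
positivity-based statistic is identical under all plausible splits, since
only the positive/negative class of each count enters those analytics.

``platelet_pathways_synthetic.tsv`` and ``interaction_edges_synthetic.tsv``
are synthetic stand-ins, not database exports: the pathway table carries
the five documented platelet alpha-granule lumen members (CLU, SPARC,
SRGN, PF4, TGFB1) plus an illustrative wider degranulation set, and the
edge list carries illustrative confidence-scored interactions among the
study's genes of interest.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cluster import pathways_from_frame
from .enumeration import EnumerationTable

#: notes on typeset rows whose per-method split is ambiguous in print
TABLE2_AMBIGUOUS_ROWS = {
    "014": "typeset as '121112'; fixture adopts (12, 111)",
    "021": "typeset as '2216'; fixture adopts (22, 16)",
}


def _data_path(name: str):
    return resources.files("ctcpanel").joinpath("data", name)


def table2_fixture() -> EnumerationTable:
    """The packaged 20-patient two-method CTC enumeration table."""
    with resources.as_file(_data_path("table2_ctc_counts.tsv")) as path:
        return EnumerationTable.read_tsv(path)


def platelet_pathways() -> dict:
    """Synthetic platelet pathway membership: {pathway_id: gene set}."""
    with resources.as_file(_data_path("platelet_pathways_synthetic.tsv")) as path:
        return pathways_from_frame(pd.read_csv(path, sep="\t"))


def interaction_edges() -> pd.DataFrame:
    """Synthetic confidence-scored gene-gene interaction edge list."""
    with resources.as_file(_data_path("interaction_edges_synthetic.tsv")) as path:
        return pd.read_csv(path, sep="\t")
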