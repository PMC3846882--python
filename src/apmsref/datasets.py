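"""Bundled worked-example data.

The human multi-tRNA-synthetase complex (MSC) comprises eight aminoacyl-tRNA
synthetases (DARS, EPRS, IARS, KARS, LARS, MARS, QARS, RARS) and three
scaffold proteins (AIMP1, AIMP2, AIMP3/EEF1E1). ``msc_ref_table`` returns
published relative enrichment factors for these eleven members plus the
nominated twelfth component TARSL2, from a streptavidin AP-MS experiment in
HEK 293T cells with AIMP1, AIMP2 and KARS as baits. Because REF is
invariant under positive rescaling of the underlying NSAF quotients, these
values double as worked-example *inputs*: feeding any positive multiple of
a column back through :func:`apmsref.enrichment.compute_ref` with the
eleven MSC members as the reference set must reproduce the column to the
printed precision.
"""

from __future__ import annotations

import pandas as pd

from apmsref.io import ReferenceSet

_MSC_REF_ROWS = [
    # gene,          uniprot,  REF with bait AIMP1, AIMP2, KARS
    ("AIMP1", "Q12904", 4.73, 1.19, 1.18),
    ("AIMP2", "Q13155", 0.69, 3.28, 1.65),
    ("DARS", "P14868", 0.65, 0.72, 0.68),
    ("EEF1E1", "O43324", 0.44, 0.18, 0.84),  # AIMP3
    ("EPRS", "P07814", 0.55, 0.84, 0.69),
    ("IARS", "P41252", 1.06, 1.60, 1.39),
    ("KARS", "Q15046", 0.80, 0.75, 3.75),
    ("LARS", "Q9P2J5", 0.89, 1.22, 0.95),
    ("MARS", "P56192", 0.35, 0.38, 0.39),
    ("QARS", "P47897", 2.95, 2.07, 1.51),
    ("RARS", "P54136", 1.62, 1.04, 0.73),
    ("TARSL2", "A2RTX5", 0.57, 0.43, 0.53),
]

MSC_BAITS = ("AIMP1", "AIMP2", "KARS")


def msc_ref_table() -> pd.DataFrame:
    """Published MSC relative enrichment factors, indexed by gene symbol.

    Columns ``AIMP1``, ``AIMP2``, ``KARS`` hold each protein's REF in that
    bait's purification; ``uniprot`` carries the accession.
    """
    table = pd.DataFrame(
        _MSC_REF_ROWS, columns=["gene", "uniprot", *MSC_BAITS]
    ).set_index("gene")
    return table


def msc_reference_set() -> ReferenceSet:
    """The eleven known MSC core members (TARSL2 excluded)."""
    members = tuple(g for g, *_ in _MSC_REF_ROWS if g != "TARSL2")
    return ReferenceSet(members)
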