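"""Bundled curated tables.

Two small reference tables of predicted *D. pseudoobscura* orthologs of
annotated *D. melanogaster* microRNAs, from a published cross-species
similarity screen: one-to-one predictions and two-copy predictions.  Each row
carries the predicted locus on the *D. pseudoobscura* assembly (NCBI
accession, 1-based inclusive coordinates) and the Muller element of the
microRNA in both species (XL and XR arms map to elements A and D).  They
exercise the translocation detector on real annotation-scale data: exactly
one of the one-to-one predictions sits on different Muller elements in the
two species, and none of the two-copy predictions do.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["predicted_new_orthologs", "predicted_two_copy_orthologs"]

# columns: dmel id, dpse chromosome accession, start, end, dmel Muller, dpse Muller
_ONE_TO_ONE = [
    ("dme-mir-4956", "NC_046683.1", 4407613, 4407712, "A", "A"),
    ("dme-mir-4959", "NC_046683.1", 7183132, 7183227, "A", "A"),
    ("dme_293", "NC_046683.1", 10364806, 10364912, "A", "A"),
    ("dme-mir-2495", "NC_046681.1", 7935176, 7935255, "B", "B"),
    ("dme_401", "NC_046681.1", 8052896, 8052975, "B", "B"),
    ("dme_282", "NC_046681.1", 12960481, 12960541, "B", "B"),
    ("dme_443", "NC_046681.1", 13700665, 13700762, "B", "B"),
    ("dme_439", "NC_046681.1", 15066171, 15066236, "B", "B"),
    ("dme-mir-4971", "NC_046681.1", 18771926, 18771991, "B", "B"),
    ("dme-mir-4984", "NC_046681.1", 20718387, 20718460, "B", "B"),
    ("dme_249", "NC_046681.1", 23301966, 23302031, "B", "B"),
    ("dme-mir-4976", "NC_046680.1", 4622992, 4623089, "C", "C"),
    ("dme_237", "NC_046680.1", 8875772, 8875870, "C", "C"),
    ("dme-mir-4979", "NC_046680.1", 13111227, 13111316, "C", "C"),
    ("dme-mir-4978", "NC_046680.1", 15054874, 15054942, "C", "C"),
    ("dme_427", "NC_046683.1", 45695309, 45695424, "D", "D"),
    ("dme_252", "NC_046683.1", 60707098, 60707189, "D", "D"),
    ("dme-mir-956", "NC_046683.1", 64904325, 64904476, "D", "D"),
    ("dme-mir-4941", "NC_046683.1", 64977320, 64977421, "D", "D"),
    ("dme_409", "NC_046679.1", 6661296, 6661415, "E", "E"),
    ("dme-mir-4944", "NC_046679.1", 7523386, 7523519, "E", "E"),
    ("dme_382", "NC_046679.1", 10326693, 10326801, "E", "E"),
    ("dme_378", "NC_046679.1", 12937728, 12937828, "E", "E"),
    ("dme-mir-4952", "NC_046679.1", 14132980, 14133092, "E", "E"),
    ("dme-mir-2281", "NC_046681.1", 21159185, 21159242, "E", "B"),
    ("dme_384", "NC_046679.1", 22587365, 22587467, "E", "E"),
]

_TWO_COPY = [
    ("dme_393", "NC_046679.1", 21527631, 21527726, "E", "E"),
    ("dme_393", "NC_046679.1", 21530842, 21530915, "E", "E"),
    ("dme-mir-4948", "NC_046679.1", 1526563, 1526662, "E", "E"),
    ("dme-mir-4948", "NC_046679.1", 2671493, 2671578, "E", "E"),
]


def _frame(rows) -> pd.DataFrame:
    df = pd.DataFrame(
        rows,
        columns=["id1", "chromosome2", "start2", "end2", "muller1", "muller2"],
    )
    df["id2"] = [
        f"{c}:{s}-{e}" for c, s, e in zip(df["chromosome2"], df["start2"], df["end2"])
    ]
    return df[["id1", "id2", "muller1", "muller2", "chromosome2", "start2", "end2"]]


def predicted_new_orthologs() -> pd.DataFrame:
    """26 predicted one-to-one orthologs (ortholog-pair table)."""
    return _frame(_ONE_TO_ONE)


def predicted_two_copy_orthologs() -> pd.DataFrame:
    """2 microRNAs with two predicted copies each (4 ortholog pairs)."""
    return _frame(_TWO_COPY)
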