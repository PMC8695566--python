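"""Gene lists used by the labeling stage and the synthetic generator.

The TGF-beta signaling pathway list carries a regulatory direction per gene:
+1 for ligands, receptors and transducers that promote pathway activity, -1
for established inhibitors of the cascade. The score built from it is a
direction-weighted average of normalized expression, so a high score marks a
TGF-beta-active (ICI-unfavorable) tumor microenvironment.

The list is editable: :func:`load_pathway` reads a two-column TSV
(gene, weight) so users can swap in their own curation.
"""

from __future__ import annotations

import pandas as pd

# Canonical TGF-beta signaling members. Direction +1: ligands/receptors/
# R-SMADs and co-activators; -1: inhibitory SMADs, E3 ligases and decoys.
TGFB_PATHWAY: tuple[tuple[str, int], ...] = (
    ("TGFB1", +1), ("TGFB2", +1), ("TGFB3", +1),
    ("TGFBR1", +1), ("TGFBR2", +1), ("TGFBR3", +1),
    ("SMAD2", +1), ("SMAD3", +1), ("SMAD4", +1),
    ("SMAD1", +1), ("SMAD5", +1), ("SMAD9", +1),
    ("ACVR1", +1), ("ACVR1B", +1), ("ACVR2A", +1), ("ACVR2B", +1),
    ("ACVRL1", +1), ("BMP2", +1), ("BMP4", +1), ("BMP6", +1), ("BMP7", +1),
    ("BMPR1A", +1), ("BMPR1B", +1), ("BMPR2", +1),
    ("INHBA", +1), ("INHBB", +1), ("GDF11", +1), ("GDF15", +1),
    ("LTBP1", +1), ("LTBP2", +1), ("THBS1", +1),
    ("SERPINE1", +1), ("SKIL", -1), ("SKI", -1),
    ("SMAD6", -1), ("SMAD7", -1),
    ("SMURF1", -1), ("SMURF2", -1),
    ("BAMBI", -1), ("FST", -1), ("FMOD", -1),
    ("LEFTY1", -1), ("LEFTY2", -1), ("NOG", -1), ("CHRD", -1),
    ("GREM1", -1), ("GREM2", -1), ("DCN", -1), ("THBS2", +1), ("ID1", +1),
)

#: Checkpoint / immune marker genes carried by the synthetic generator and
#: used downstream as validation biomarkers (PD-L1 drives an indicator test;
#: PD-1 and CTLA4 are held out for biomarker-separation checks).
MARKER_GENES: tuple[str, ...] = ("CD274", "PDCD1", "CTLA4")


def default_pathway() -> pd.DataFrame:
    """The built-in TGF-beta pathway as a (gene, weight) table."""
    return pd.DataFrame(TGFB_PATHWAY, columns=["gene", "weight"])


def load_pathway(path) -> pd.DataFrame:
    """Read a pathway TSV with columns ``gene`` and ``weight`` (+1/-1)."""
    tab = pd.read_csv(path, sep="\t", comment="#")
    if not {"gene", "weight"}.issubset(tab.columns):
        raise ValueError("pathway file needs 'gene' and 'weight' columns")
    if not tab["weight"].abs().eq(1).all():
        raise ValueError("pathway weights must be +1 or -1")
    return tab[["gene", "weight"]]
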