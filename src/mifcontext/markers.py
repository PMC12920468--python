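"""Marker vocabulary and staining-panel layout.

Three multiplex-immunofluorescence panels are stained on serial sections of
the same block.  Each panel carries cytokeratin (CK, epithelial tumor mask)
plus five immune markers; together the panels cover the 14-marker
vocabulary used throughout the package.
"""

from __future__ import annotations

#: Full marker vocabulary (14 markers), canonical spellings.
MARKERS: tuple[str, ...] = (
    "CK", "CD20", "CD11c", "CD163", "CD15", "CD56", "CD3",
    "CD4", "CD8", "Foxp3", "GrzB", "Ki67", "PD-1", "PD-L1",
)

#: Markers available on each staining panel.
#: P1 — overall immune composition (B cells, DC, neutrophils, macrophages, T cells)
#: P2 — cytotoxic and functional markers (checkpoint axis)
#: P3 — T-cell subsets and NK cells
PANEL_MARKERS: dict[str, frozenset[str]] = {
    "P1": frozenset({"CK", "CD20", "CD11c", "CD15", "CD3", "CD163"}),
    "P2": frozenset({"CK", "PD-1", "CD8", "PD-L1", "Ki67", "GrzB"}),
    "P3": frozenset({"CK", "CD3", "CD4", "Foxp3", "CD56", "CD8"}),
}

PANELS: tuple[str, ...] = tuple(PANEL_MARKERS)

#: Canonical phenotype labels → (default panel, defining positive markers).
#: A phenotype may be measurable on more than one panel (CD3 on P1/P3, CD8 on
#: P2/P3); the default panel is the one used by the scoring machinery.
PHENOTYPE_MARKERS: dict[str, tuple[str, frozenset[str]]] = {
    "CD20+": ("P1", frozenset({"CD20"})),
    "CD11c+": ("P1", frozenset({"CD11c"})),
    "CD15+": ("P1", frozenset({"CD15"})),
    "CD163+": ("P1", frozenset({"CD163"})),
    "CD3+": ("P3", frozenset({"CD3"})),
    "CD8+": ("P2", frozenset({"CD8"})),
    "CD4+": ("P3", frozenset({"CD4"})),
    "PD-1+": ("P2", frozenset({"PD-1"})),
    "PD-L1+": ("P2", frozenset({"PD-L1"})),
    "GrzB+": ("P2", frozenset({"GrzB"})),
    "Ki67+": ("P2", frozenset({"Ki67"})),
    "CD56+": ("P3", frozenset({"CD56"})),
    "CD8+PD-1+": ("P2", frozenset({"CD8", "PD-1"})),
    "CD4+Foxp3+": ("P3", frozenset({"CD4", "Foxp3"})),
    "CK+": ("P2", frozenset({"CK"})),
}


def default_panel(phenotype: str) -> str:
    """Default staining panel for a canonical phenotype label."""
    try:
        return PHENOTYPE_MARKERS[phenotype][0]
    except KeyError:
        raise KeyError(f"unknown phenotype label: {phenotype!r}") from None
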