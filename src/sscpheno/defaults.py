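"""Bundled defaults: a 64-plex immuno-oncology style protein panel, the
hierarchical gate library for B-lineage/plasma-cell phenotyping, and the
default phenotyping exclusion list.

The panel mirrors the structure of commercial 64-plex tissue-imaging protein
panels: 62 gateable targets plus one isotype-control channel per host class
(mouse IgG1 and rabbit IgG), which set the positivity cut-offs of 30 and 100
fluorescence units respectively. Any other panel can be supplied as a CSV;
nothing below is hard-wired into the algorithms.
"""

from __future__ import annotations

from .panel_io import MOUSE_IGG1, RABBIT_IGG, Panel, PanelTarget

#: Rabbit-hosted targets (cut-off 100); every other target is mouse IgG1
#: hosted (cut-off 30).
_RABBIT_HOSTED = {
    "Beta-catenin",
    "NFkB-p65",
    "Pan-RAS",
    "Fibronectin",
    "STING",
    "Bcl-2",
    "IDO1",
    "iNOS",
}

#: 62 gateable target names (isotype controls excluded).
DEFAULT_TARGETS = [
    # structural / lineage anchors
    "Vimentin", "EpCAM", "PanCK", "B2M/CD298", "Fibronectin", "SMA",
    "Beta-catenin", "EGFR", "HER2",
    # B lineage / plasma cell
    "CD19", "CD20", "CD21", "CD23", "CD27", "CD38", "CD45", "CD138",
    "BCMA", "IgD", "Ki-67", "NFkB-p65", "Pan-RAS", "Bcl-2",
    # T / NK / myeloid
    "CD3", "CD4", "CD8", "CD56", "CD11c", "CD11b", "CD14", "CD16",
    "CD25", "CD68", "CD163", "FOXP3", "HLA-DR", "GZMB", "iNOS",
    # checkpoint / activation
    "PD-1", "PD-L1", "PD-L2", "CTLA4", "LAG3", "TIM-3", "ICOS",
    "OX40L", "4-1BB", "GITR", "IDO1", "B7-H3", "VISTA", "CD40",
    "CD86", "CD127", "CD30", "CD39", "CD15", "CD66b",
    # adhesion / vasculature / misc
    "CD31", "CD34", "CD44", "STING",
]

MOUSE_CONTROL = "Ms-IgG1-ctrl"
RABBIT_CONTROL = "Rb-IgG-ctrl"


def default_panel() -> Panel:
    """The bundled 64-plex panel: 62 targets + 2 isotype controls."""
    targets = [
        PanelTarget(
            name=n,
            host=RABBIT_IGG if n in _RABBIT_HOSTED else MOUSE_IGG1,
        )
        for n in DEFAULT_TARGETS
    ]
    targets.append(PanelTarget(MOUSE_CONTROL, MOUSE_IGG1, is_isotype_control=True))
    targets.append(PanelTarget(RABBIT_CONTROL, RABBIT_IGG, is_isotype_control=True))
    return Panel(targets)


#: Targets unrelated to the B-cell compartment, excluded by default from
#: plasma-cell phenotyping (continuous summaries and embeddings).
DEFAULT_PHENOTYPING_EXCLUSIONS = [
    "Beta-catenin",
    "CD16",
    "CD3",
    "CD4",
    "CD56",
    "CD68",
    "CD8",
    "EGFR",
    "EpCAM",
    "Fibronectin",
    "FOXP3",
    "HER2",
    "SMA",
]

#: Named gate library. A cell satisfies a gate iff every listed marker has
#: the required sign in the positivity matrix. Lamina-propria (LP) residency
#: is Vimentin positivity; plasma cells (PCs) are Vim+CD138+; plasmablasts
#: (PBs) are Vim+CD19+CD27+CD38+CD20-CD138-.
DEFAULT_GATES: dict[str, dict[str, str]] = {
    "LP_immune": {"Vimentin": "+"},
    "PC": {"Vimentin": "+", "CD138": "+"},
    "PB": {
        "Vimentin": "+",
        "CD19": "+",
        "CD27": "+",
        "CD38": "+",
        "CD20": "-",
        "CD138": "-",
    },
    "epithelial": {"EpCAM": "+"},
}

#: Plasma-cell maturation subtypes, resolved from the CD19/CD45 signs of
#: cells inside the PC gate. "other" is CD19+CD45-, the one combination the
#: three named maturation stages leave over.
PC_SUBTYPE_GATES: dict[str, dict[str, str]] = {
    "CD19+CD45+": {"CD19": "+", "CD45": "+"},
    "CD19-CD45+": {"CD19": "-", "CD45": "+"},
    "CD19-CD45-": {"CD19": "-", "CD45": "-"},
    "other": {"CD19": "+", "CD45": "-"},
}

PC_SUBTYPES = list(PC_SUBTYPE_GATES)
NOT_A_PC = "not_a_PC"
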