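"""Reference metadata for the public trigger-recognition corpora.

The corpora themselves (MLEE, BioNLP'09 Shared Task, BioNLP'11 EPI) are
licensed downloads and are never bundled; what this module records are their
published trigger-type inventories and document counts, which drive
label-overlap analysis and source/target size arithmetic without any data on
disk.  Label names use the standoff convention (underscores for spaces).
"""

from __future__ import annotations

from .corpus_io import LabelSet, OverlapPartition, compute_label_overlap

#: BioNLP'09 Shared Task: 9 molecular-level event types.
ST09_TRIGGER_TYPES = (
    "Gene_expression",
    "Transcription",
    "Binding",
    "Protein_catabolism",
    "Phosphorylation",
    "Localization",
    "Regulation",
    "Positive_regulation",
    "Negative_regulation",
)

#: BioNLP'11 EPI task: 14 protein-modification event types plus Catalysis.
EPI11_TRIGGER_TYPES = (
    "Hydroxylation",
    "Dehydroxylation",
    "Phosphorylation",
    "Dephosphorylation",
    "Ubiquitination",
    "Deubiquitination",
    "DNA_methylation",
    "DNA_demethylation",
    "Glycosylation",
    "Deglycosylation",
    "Acetylation",
    "Deacetylation",
    "Methylation",
    "Demethylation",
    "Catalysis",
)

#: MLEE: 19 event types spanning molecular to organism level.
MLEE_TRIGGER_TYPES = (
    "Cell_proliferation",
    "Development",
    "Blood_vessel_development",
    "Growth",
    "Death",
    "Breakdown",
    "Remodeling",
    "Synthesis",
    "Gene_expression",
    "Transcription",
    "Protein_catabolism",
    "Phosphorylation",
    "Dephosphorylation",
    "Localization",
    "Binding",
    "Regulation",
    "Positive_regulation",
    "Negative_regulation",
    "Planned_process",
)

#: Published document (abstract) counts.
MLEE_DOCUMENTS = {"train": 131, "dev": 44, "test": 87, "total": 262}
ST09_DOCUMENTS = {"train": 800, "dev": 150, "total": 950}
EPI11_DOCUMENTS = {"train": 600, "dev": 200, "total": 800}


def st09_label_set() -> LabelSet:
    return LabelSet(ST09_TRIGGER_TYPES)


def epi11_label_set() -> LabelSet:
    return LabelSet(EPI11_TRIGGER_TYPES)


def mlee_label_set() -> LabelSet:
    return LabelSet(MLEE_TRIGGER_TYPES)


def st09_mlee_overlap() -> OverlapPartition:
    """The 9 trigger types shared between the molecular-level source
    inventory and the multiple-level target inventory."""
    return compute_label_overlap(st09_label_set(), mlee_label_set())


def epi11_mlee_overlap() -> OverlapPartition:
    """The 2 trigger types (phosphorylation and its reversal) shared between
    the protein-modification source inventory and the target inventory."""
    return compute_label_overlap(epi11_label_set(), mlee_label_set())
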