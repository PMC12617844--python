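"""Canonical ROI label handling for the 133-region parcellation.

The analysis operates on 133 regions: 91 cortical and 15 subcortical
Harvard-Oxford regions, 26 AAL cerebellar regions, and one AAL olfactory
region. The full published abbreviation list is not redistributable here, so
:func:`default_roi_labels` builds a synthetic stand-in: the abbreviations
that matter for the analysis (the olfactory and brainstem hubs and the
limbic/opercular regions reported alongside them) use their field-standard
Harvard-Oxford short names, and the remainder are systematic placeholders.
Label matching everywhere is case-insensitive and whitespace-normalized.
"""

from __future__ import annotations

N_ROIS = 133

# Harvard-Oxford style abbreviations used by the connectivity tables.
_NAMED = [
    "Olfactory",
    "Brainstem",
    "FO r", "FO l",
    "IC r", "IC l",
    "CO r", "CO l",
    "PO r", "PO l",
    "PP r", "PP l",
    "PT r", "PT l",
    "HG r", "HG l",
    "AC",
    "PaCiG r", "PaCiG l",
    "SMA r", "SMA l",
    "FOrb r", "FOrb l",
    "IFG tri r", "IFG tri l",
    "IFG oper r", "IFG oper l",
    "aSTG r", "aSTG l",
    "aPaHC r", "aPaHC l",
    "pPaHC r", "pPaHC l",
    "aTFusC r", "aTFusC l",
    "pTFusC r", "pTFusC l",
    "aITG r", "aITG l",
    "pITG r", "pITG l",
    "TP r", "TP l",
    "FP r", "FP l",
    "SFG r", "SFG l",
    "MidFG r", "MidFG l",
    "PreCG r", "PreCG l",
    "Hippocampus r", "Hippocampus l",
    "Amygdala r", "Amygdala l",
    "Putamen r", "Putamen l",
    "Pallidum r", "Pallidum l",
    "Caudate r", "Caudate l",
    "Thalamus r", "Thalamus l",
]


def normalize_label(label: str) -> str:
    """Case-insensitive, whitespace-collapsed canonical form of a label."""
    return " ".join(label.strip().split()).lower()


def default_roi_labels(n_rois: int = N_ROIS) -> list[str]:
    """Synthetic stand-in for the canonical 133-ROI label list.

    The named abbreviations come first (hubs and the regions the connection
    tables report); cortical/cerebellar placeholders pad the list to
    ``n_rois``. Placeholder names mimic the atlas mix: "Ctx NN r/l" for the
    remaining cortex and "Cereb NN" for the cerebellum.
    """
    labels = list(_NAMED[:n_rois])
    i = 1
    while len(labels) < max(0, n_rois - 26):
        side = "r" if i % 2 else "l"
        labels.append(f"Ctx {((i + 1) // 2):02d} {side}")
        i += 1
    j = 1
    while len(labels) < n_rois:
        labels.append(f"Cereb {j:02d}")
        j += 1
    return labels[:n_rois]


def match_order(labels: list[str], canonical: list[str]) -> list[int]:
    """Permutation mapping ``canonical`` positions to indices in ``labels``.

    Raises ``ValueError`` naming the offending labels when the two sets do
    not coincide (after normalization).
    """
    lookup = {normalize_label(l): i for i, l in enumerate(labels)}
    if len(lookup) != len(labels):
        raise ValueError("duplicate ROI labels after normalization")
    missing = [c for c in canonical if normalize_label(c) not in lookup]
    extra = [l for l in labels if normalize_label(l) not in
             {normalize_label(c) for c in canonical}]
    if missing or extra:
        raise ValueError(
            f"ROI label mismatch: missing {missing[:5]}, unexpected {extra[:5]}"
        )
    return [lookup[normalize_label(c)] for c in canonical]
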