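"""Published confusion matrices of the emulated study.

The original tactile-enhanced-multimedia study never released its raw
recordings, but it did print the 4x4 confusion matrices of its KNN
classifier for each modality (EEG, GSR, PPG) and for the three-modality
fusion, over 84 sessions in the canonical class order (relaxed, sad,
happy, angry).  Those printed counts are shipped here as plain CSV
inputs so every derived metric — accuracy, Cohen's kappa, per-class
rates — can be recomputed from first principles and checked against the
study's reported values.

Note: in the GSR, PPG and fusion matrices as printed, the *column* sums
(not the row sums) equal the study's actual class counts (9, 22, 40,
13), i.e. those three appear transposed relative to the EEG matrix.
Accuracy and kappa are invariant to transposition, so they are safe on
all four; per-class row/column rates should only be trusted on the EEG
matrix, whose row sums match the class counts.
"""

from __future__ import annotations

from importlib import resources

from .evaluation import ConfusionMatrix

__all__ = ["STUDY_MODALITIES", "load_study_confusion"]

STUDY_MODALITIES: tuple[str, ...] = ("eeg", "gsr", "ppg", "fusion")


def load_study_confusion(modality: str) -> ConfusionMatrix:
    """Load one of the study's printed confusion matrices by modality name.

    ``modality`` is one of ``"eeg"``, ``"gsr"``, ``"ppg"`` or
    ``"fusion"`` (the EEG+GSR+PPG modality-level fusion).
    """
    if modality not in STUDY_MODALITIES:
        raise ValueError(f"modality must be one of {STUDY_MODALITIES}")
    path = resources.files("temsense.data") / f"confusion_{modality}.csv"
    with resources.as_file(path) as p:
        return ConfusionMatrix.from_csv(p)
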