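"""Speaker classes used throughout the package.

Long-form child-audio diarization distinguishes four voice types: the key
child wearing the recorder (CHI), other children (OCH), female adults (FEM)
and male adults (MAL). All confusion matrices and count vectors in this
package are indexed in this fixed order.
"""

from __future__ import annotations

from enum import IntEnum


class SpeakerClass(IntEnum):
    """The four voice types, with a stable index order used by all matrices."""

    CHI = 0
    OCH = 1
    FEM = 2
    MAL = 3

    @classmethod
    def from_label(cls, label: str) -> "SpeakerClass":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise KeyError(f"unknown speaker label: {label!r}") from None


N_CLASSES = 4
SPEAKERS = tuple(SpeakerClass)
SPEAKER_LABELS = tuple(s.name for s in SpeakerClass)
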