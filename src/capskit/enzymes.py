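"""Restriction enzymes: recognition motifs and cut offsets.

The bundled table (``data/enzymes.tsv``) holds a small set of common
type-II enzymes, including BspHI (T^CATGA) used for the fire-ant COX1
marker.  ``cut_offset`` is the 0-based position of the top-strand cut
within the recognition sequence, so BspHI has offset 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .exceptions import FormatError
from .iupac import IUPAC_CODES, is_palindromic


@dataclass(frozen=True)
class Enzyme:
    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        object.__setattr__(self, "recognition", rec)
        if not rec or any(c not in IUPAC_CODES for c in rec):
            raise ValueError(f"{self.name}: recognition {rec!r} is not IUPAC DNA")
        if not 0 <= self.cut_offset <= len(rec):
            raise ValueError(
                f"{self.name}: cut offset {self.cut_offset} outside 0..{len(rec)}"
            )

    @property
    def palindromic(self) -> bool:
        return is_palindromic(self.recognition)


def load_enzymes(path: str | Path | None = None) -> list[Enzyme]:
    """Read an enzyme table (TSV: name, recognition, cut_offset).

    With no path, returns the bundled default table.
    """
    if path is None:
        text = (resources.files("capskit.data") / "enzymes.tsv").read_text()
    else:
        text = Path(path).read_text()
    enzymes: list[Enzyme] = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty enzyme table")
    start = 1 if lines[0].lower().startswith("name") else 0
    for ln in lines[start:]:
        fields = ln.split("\t")
        if len(fields) != 3:
            raise FormatError(f"bad enzyme line: {ln!r}")
        try:
            enzymes.append(Enzyme(fields[0], fields[1], int(fields[2])))
        except ValueError as exc:
            raise FormatError(str(exc)) from exc
    return enzymes
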