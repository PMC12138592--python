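"""Input-card parsing and serialization.

A card is a plain-text instruction file driving an overlay run.  The grammar
is line-oriented, whitespace-tokenized:

* an optional first non-comment line ``#REF <path> [<chain>]`` naming the
  reference structure;
* ``#G <groupname>`` lines opening display groups;
* entry lines, one structure each::

      <coords> [<map: .mtz/.ccp4/.mrc/.map>] <ligand chain> <resi|lo-hi> <name> [<align chain>]

Any other line whose first token starts with ``#`` is a comment.  Residue
ranges accept both a hyphen and an en-dash separator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

__all__ = [
    "EntrySpec",
    "InputCard",
    "CardError",
    "parse_card",
    "serialize_card",
    "load_card",
]

#: Extensions that mark the optional second token as a map file.
MAP_EXTENSIONS = {".mtz", ".ccp4", ".mrc", ".map"}

_RANGE_RE = re.compile(r"^(\d+)(?:[-–](\d+))?$")


class CardError(ValueError):
    """Raised for malformed or invalid input cards."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class EntrySpec:
    """One structure to be added to the scene."""

    coord_path: str
    ligand_chain: str
    ligand_resrange: tuple[int, int]
    object_name: str
    map_path: Optional[str] = None
    align_chain: Optional[str] = None

    def __post_init__(self) -> None:
        lo, hi = self.ligand_resrange
        if lo > hi:
            raise CardError(f"residue range {lo}-{hi} has lo > hi")
        if not self.object_name or any(c.isspace() for c in self.object_name):
            raise CardError(f"invalid object name {self.object_name!r}")


@dataclass
class InputCard:
    """Parsed card: optional reference plus ordered entry groups."""

    reference: Optional[tuple[str, Optional[str]]] = None
    groups: list[tuple[str, list[EntrySpec]]] = field(default_factory=list)

    @property
    def entries(self) -> list[EntrySpec]:
        return [e for _, members in self.groups for e in members]

    def validate(self) -> None:
        names = [g for g, _ in self.groups]
        if len(set(names)) != len(names):
            raise CardError("duplicate group names in card")
        seen: set[str] = set()
        for entry in self.entries:
            if entry.object_name in seen:
                raise CardError(f"duplicate object name {entry.object_name!r}")
            seen.add(entry.object_name)


def _parse_resrange(token: str, line_no: int) -> tuple[int, int]:
    m = _RANGE_RE.match(token)
    if not m:
        raise CardError(f"malformed residue range {token!r}", line_no)
    lo = int(m.group(1))
    hi = int(m.group(2)) if m.group(2) else lo
    if lo > hi:
        raise CardError(f"residue range {token!r} has lo > hi", line_no)
    return lo, hi


def _parse_entry(tokens: list[str], line_no: int) -> EntrySpec:
    if len(tokens) < 4:
        raise CardError(
            "entry needs at least <coords> <chain> <resrange> <name>", line_no
        )
    coord_path = tokens[0]
    i = 1
    map_path = None
    if Path(tokens[1]).suffix.lower() in MAP_EXTENSIONS:
        map_path = tokens[1]
        i = 2
    rest = tokens[i:]
    if len(rest) < 3 or len(rest) > 4:
        raise CardError(f"cannot parse entry tokens {tokens!r}", line_no)
    ligand_chain = rest[0]
    resrange = _parse_resrange(rest[1], line_no)
    object_name = rest[2]
    align_chain = rest[3] if len(rest) == 4 else None
    try:
        return EntrySpec(
            coord_path=coord_path,
            map_path=map_path,
            ligand_chain=ligand_chain,
            ligand_resrange=resrange,
            object_name=object_name,
            align_chain=align_chain,
        )
    except CardError as exc:
        raise CardError(str(exc), line_no) from None


def parse_card(text: str) -> InputCard:
    """Parse card text into an :class:`InputCard`.

    Raises :class:`CardError` (with the offending line number) on entries
    outside any group, malformed ranges, misplaced ``#REF``, or duplicate
    object/group names.
    """
    card = InputCard()
    current_group: Optional[list[EntrySpec]] = None
    seen_content = False
    for line_no, raw in enumerate(text.splitlines(), start=1):
        tokens = raw.split()
        if not tokens:
            continue
        tag = tokens[0]
        if tag == "#REF":
            if seen_content or card.reference is not None:
                raise CardError("#REF must be the first non-comment line", line_no)
            if len(tokens) not in (2, 3):
                raise CardError("#REF takes <path> [<chain>]", line_no)
            card.reference = (tokens[1], tokens[2] if len(tokens) == 3 else None)
            seen_content = True
        elif tag == "#G":
            if len(tokens) != 2:
                raise CardError("#G takes exactly one group name", line_no)
            current_group = []
            card.groups.append((tokens[1], current_group))
            seen_content = True
        elif tag.startswith("#"):
            continue  # comment
        else:
            if current_group is None:
                raise CardError("entry outside group (no #G seen yet)", line_no)
            current_group.append(_parse_entry(tokens, line_no))
            seen_content = True
    card.validate()
    return card


def serialize_card(card: InputCard) -> str:
    """Render a card back to text; ``parse_card`` round-trips it exactly."""
    lines: list[str] = []
    if card.reference is not None:
        path, chain = card.reference
        lines.append(f"#REF {path}" + (f" {chain}" if chain else ""))
    for group_name, members in card.groups:
        lines.append(f"#G {group_name}")
        for e in members:
            lo, hi = e.ligand_resrange
            rng = str(lo) if lo == hi else f"{lo}-{hi}"
            tokens = [e.coord_path]
            if e.map_path is not None:
                tokens.append(e.map_path)
            tokens += [e.ligand_chain, rng, e.object_name]
            if e.align_chain is not None:
                tokens.append(e.align_chain)
            lines.append(" ".join(tokens))
    return "\n".join(lines) + ("\n" if lines else "")


def load_card(path: str | Path) -> InputCard:
    """Read a card file; relative entry paths resolve against the card's
    directory so cards can be shared between working directories."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise CardError(f"cannot read card {path}: {exc}") from exc
    card = parse_card(text)
    base = path.parent

    def _resolve(p: Optional[str]) -> Optional[str]:
        if p is None:
            return None
        q = Path(p)
        return str(q if q.is_absolute() else base / q)

    if card.reference is not None:
        rp, rc = card.reference
        card.reference = (_resolve(rp), rc)
    card.groups = [
        (
            g,
            [
                replace(e, coord_path=_resolve(e.coord_path), map_path=_resolve(e.map_path))
                for e in members
            ],
        )
        for g, members in card.groups
    ]
    return card
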