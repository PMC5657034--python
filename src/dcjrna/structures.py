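"""Component-based model and I/O for RNA secondary structures.

An RNA secondary structure is modelled as an ordered list of *components*.
A component is one maximal helix: a run of stacked base pairs with no
interruption (bulge or internal loop) on either strand.  It is recorded by
three integers, all 1-based:

``ob``
    position of the first base of the opening (5') strand,
``cb``
    position of the first base of the closing (3') strand,
``stem_len``
    number of base pairs in the helix.

The opening strand therefore occupies ``ob .. ob+stem_len-1`` and the
closing strand ``cb .. cb+stem_len-1``; the component's full span is the
closed interval ``[ob, cb+stem_len-1]``.

Structures may additionally carry intermolecular (INTERM) component records
for interacting patterns; these are preserved verbatim but never matched or
rearranged.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace

__all__ = [
    "Component",
    "SecondaryStructure",
    "StructureError",
    "ParseError",
    "ValidationError",
    "full_length",
    "parse_component_text",
    "parse_dotbracket",
    "to_dotbracket",
    "read_structure_file",
]


class StructureError(ValueError):
    """Base class for structure parsing/validation failures."""


class ParseError(StructureError):
    """Input text does not match the expected grammar or notation."""


class ValidationError(StructureError):
    """A structure violates a model invariant (overlap, out of range...)."""


@dataclass(frozen=True)
class Component:
    """One maximal helix of a secondary structure."""

    index: int
    ob: int
    cb: int
    stem_len: int

    @property
    def span(self) -> tuple[int, int]:
        """Closed interval covered by the helix, first to last base."""
        return (self.ob, self.cb + self.stem_len - 1)

    @property
    def loop(self) -> tuple[int, int]:
        """Closed interval strictly between the two strands."""
        return (self.ob + self.stem_len, self.cb - 1)


def full_length(c: Component) -> int:
    """Number of bases from the first opening-strand base through the last
    closing-strand base: ``cb + stem_len - ob``."""
    return c.cb + c.stem_len - c.ob


@dataclass(frozen=True)
class SecondaryStructure:
    """A secondary structure: total length plus ordered helix components.

    Components are sorted by ``ob``, indexed consecutively from 1, and must
    be non-crossing: any two spans are disjoint, or the inner one lies
    entirely within the outer component's loop region (pseudoknots are out
    of scope).
    """

    name: str
    length: int
    components: tuple[Component, ...]
    interm: tuple[tuple[int, ...], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError(f"{self.name}: length must be positive")
        object.__setattr__(self, "components", tuple(self.components))
        object.__setattr__(self, "interm", tuple(tuple(t) for t in self.interm))
        self._validate()

    def _validate(self) -> None:
        comps = self.components
        for k, c in enumerate(comps, start=1):
            tag = f"{self.name}: component {c.index}"
            if c.index != k:
                raise ValidationError(f"{tag}: indices must run 1..{len(comps)}")
            if c.ob < 1 or c.stem_len < 1:
                raise ValidationError(f"{tag}: ob and stem length must be >= 1")
            if c.ob + c.stem_len > c.cb:
                raise ValidationError(
                    f"{tag}: closing strand (cb={c.cb}) must start after the "
                    f"opening strand ends (ob+stem_len={c.ob + c.stem_len})"
                )
            if c.span[1] > self.length:
                raise ValidationError(
                    f"{tag}: span ends at {c.span[1]} beyond length {self.length}"
                )
        for i in range(1, len(comps)):
            if comps[i].ob <= comps[i - 1].ob:
                raise ValidationError(
                    f"{self.name}: components must be strictly ordered by ob"
                )
        # non-crossing: later component starts inside an earlier span only
        # if it fits entirely inside that component's loop
        for i, outer in enumerate(comps):
            for inner in comps[i + 1 :]:
                if inner.ob > outer.span[1]:
                    continue  # disjoint, inner is to the right
                lo, hi = outer.loop
                if not (lo <= inner.ob and inner.span[1] <= hi):
                    raise ValidationError(
                        f"{self.name}: components {outer.index} and "
                        f"{inner.index} cross or overlap a stem"
                    )

    def __len__(self) -> int:
        return len(self.components)

    def with_name(self, name: str) -> "SecondaryStructure":
        return replace(self, name=name)

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "length": self.length,
                "intram": [[c.ob, c.cb, c.stem_len] for c in self.components],
                "interm": [list(t) for t in self.interm],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SecondaryStructure":
        try:
            d = json.loads(text)
            comps = tuple(
                Component(i, ob, cb, sl)
                for i, (ob, cb, sl) in enumerate(d["intram"], start=1)
            )
            return cls(
                name=d["name"],
                length=int(d["length"]),
                components=comps,
                interm=tuple(tuple(t) for t in d.get("interm", [])),
            )
        except (KeyError, TypeError, json.JSONDecodeError) as exc:
            raise ParseError(f"bad structure JSON: {exc}") from exc

    @classmethod
    def from_tuples(
        cls,
        name: str,
        length: int,
        tuples: "list[tuple[int, int, int]]",
        interm: "tuple[tuple[int, ...], ...]" = (),
    ) -> "SecondaryStructure":
        """Build from unindexed (ob, cb, stem_len) tuples; sorts by ob."""
        ordered = sorted(tuples, key=lambda t: t[0])
        comps = tuple(
            Component(i, ob, cb, sl) for i, (ob, cb, sl) in enumerate(ordered, 1)
        )
        return cls(name=name, length=length, components=comps, interm=interm)


# --- component-notation grammar ------------------------------------------
#
#   Name = (length, INTERM = {...}, INTRAM = {a_1 = (ob, cb, len), ...})
#
# Subscript underscores (a_1_) and the misspelling INRAM are accepted.

_COMP_RE = re.compile(
    r"\s*(?P<id>\w+?)_?\s*=\s*\(\s*(?P<nums>\d+(?:\s*,\s*\d+)*)\s*\)\s*"
)


def parse_component_text(text: str) -> SecondaryStructure:
    """Parse one structure in component notation.

    Grammar: ``Name = (length, INTERM = {...}, INTRAM = {id = (ob, cb,
    len), ...})``.  ``INRAM`` is accepted as a spelling of ``INTRAM``.
    """
    normalized = re.sub(r"\bIN\s*RAM\b|\bINRAM\b", "INTRAM", text.strip())
    m = re.match(
        r"^\s*(?P<name>\w+)\s*=\s*\(\s*(?P<length>\d+)\s*,"
        r"\s*INTERM\s*=\s*\{(?P<interm>[^{}]*)\}\s*,"
        r"\s*INTRAM\s*=\s*\{(?P<intram>.*)\}\s*\)\s*$",
        normalized,
        flags=re.DOTALL,
    )
    if m is None:
        raise ParseError(
            "text does not match 'Name = (length, INTERM = {...}, "
            f"INTRAM = {{...}})': {text[:80]!r}"
        )
    name = m.group("name")
    length = int(m.group("length"))
    intram = _parse_tuple_block(m.group("intram"), arity=3, label="INTRAM")
    interm = _parse_tuple_block(m.group("interm"), arity=4, label="INTERM")
    return SecondaryStructure.from_tuples(
        name, length, [tuple(t) for t in intram], interm=tuple(tuple(t) for t in interm)
    )


def _parse_tuple_block(block: str, arity: int, label: str) -> list[list[int]]:
    block = block.strip()
    if not block:
        return []
    out: list[list[int]] = []
    pos = 0
    for m in _COMP_RE.finditer(block):
        if block[pos : m.start()].strip(", \t\n"):
            raise ParseError(
                f"{label}: unexpected token {block[pos:m.start()].strip()!r}"
            )
        nums = [int(x) for x in re.split(r"\s*,\s*", m.group("nums"))]
        if len(nums) != arity:
            raise ParseError(
                f"{label} entry {m.group('id')!r}: expected {arity} integers, "
                f"got {len(nums)}"
            )
        out.append(nums)
        pos = m.end()
    if block[pos:].strip(", \t\n"):
        raise ParseError(f"{label}: trailing junk {block[pos:].strip()!r}")
    return out


# --- dot-bracket ----------------------------------------------------------


def parse_dotbracket(line: str, name: str = "structure") -> SecondaryStructure:
    """Decompose a dot-bracket string into maximal helices.

    A helix ends at any interruption of stacking: consecutive pairs must be
    (i, j), (i+1, j-1), ... on *both* strands.
    """
    line = line.strip()
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []  # (i, j), 1-based, i < j
    for pos, ch in enumerate(line, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ParseError(f"{name}: unmatched ')' at position {pos}")
            pairs.append((stack.pop(), pos))
        elif ch != ".":
            raise ParseError(f"{name}: illegal character {ch!r} at position {pos}")
    if stack:
        raise ParseError(f"{name}: unmatched '(' at position {stack[-1]}")

    pairs.sort()
    helices: list[tuple[int, int, int]] = []  # (ob, cb, stem_len)
    cur: list[tuple[int, int]] = []
    for p in pairs:
        if cur and p == (cur[-1][0] + 1, cur[-1][1] - 1):
            cur.append(p)
        else:
            if cur:
                helices.append((cur[0][0], cur[-1][1], len(cur)))
            cur = [p]
    if cur:
        helices.append((cur[0][0], cur[-1][1], len(cur)))
    return SecondaryStructure.from_tuples(name, max(len(line), 1), helices)


def to_dotbracket(s: SecondaryStructure) -> str:
    """Render a (validated, non-crossing) structure as dot-bracket text."""
    chars = ["."] * s.length
    for c in s.components:
        for k in range(c.stem_len):
            chars[c.ob - 1 + k] = "("
            chars[c.cb - 1 + k] = ")"
    return "".join(chars)


def read_structure_file(path: str) -> SecondaryStructure:
    """Read one structure from a file, auto-detecting the notation.

    Accepted layouts: a JSON object, a component-notation line, a bare
    dot-bracket line, or a FASTA-like ``>name`` header followed by one
    dot-bracket line.
    """
    with open(path) as fh:
        text = fh.read()
    stripped = text.strip()
    if not stripped:
        raise ParseError(f"{path}: empty file")
    if stripped.startswith("{"):
        return SecondaryStructure.from_json(stripped)
    lines = [ln.strip() for ln in stripped.splitlines() if ln.strip()]
    if lines[0].startswith(">"):
        if len(lines) < 2:
            raise ParseError(f"{path}: header without a structure line")
        return parse_dotbracket(lines[1], name=lines[0][1:].strip() or path)
    if set(lines[0]) <= {"(", ")", "."}:
        return parse_dotbracket(lines[0], name=path)
    return parse_component_text(stripped)
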