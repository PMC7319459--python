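"""Registry of published base editors and a parser/validator for custom ones.

Each editor is described by its deamination chemistry (C>T for cytosine base
editors, A>G for adenine base editors — always stated on the protospacer
strand), its PAM as an IUPAC pattern, which side of the protospacer the PAM
sits on (3' for type II Cas, 5' for type V/Cas12a), the gRNA/protospacer
length, and its major and minor activity windows given as inclusive
distance-from-PAM intervals (the protospacer base adjacent to the PAM is
distance 1).
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .seqcore import IUPAC_CODES

__all__ = [
    "BaseEditor",
    "EditorRegistry",
    "EditorValidationError",
    "THREE_PRIME",
    "FIVE_PRIME",
    "builtin_registry",
    "load_custom_editors",
]

THREE_PRIME = "three_prime"  # PAM downstream (3') of the protospacer, type II Cas
FIVE_PRIME = "five_prime"  # PAM upstream (5'), type V Cas (Cas12a)

_CONVERSIONS = ("C>T", "A>G")
_PAM_SIDES = (THREE_PRIME, FIVE_PRIME)


class EditorValidationError(ValueError):
    """A base-editor definition violates a structural constraint; the message
    names the offending field."""


def _normalize_conversion(value: str) -> str:
    v = value.strip().upper().replace("→", ">").replace("->", ">").replace(" ", "")
    if v in ("CT", "CTOT"):
        v = "C>T"
    if v in ("AG", "ATOG"):
        v = "A>G"
    return v


def _normalize_pam_side(value: str) -> str:
    v = value.strip().lower().replace("'", "").replace("-", "_")
    if v in ("3", "3prime", "three_prime", "downstream"):
        return THREE_PRIME
    if v in ("5", "5prime", "five_prime", "upstream"):
        return FIVE_PRIME
    return v


@dataclass(frozen=True)
class BaseEditor:
    """One base editor (or one family of constructs sharing all parameters)."""

    name: str
    conversion: str  # "C>T" or "A>G", on the protospacer strand
    pam: str  # IUPAC pattern
    pam_side: str  # THREE_PRIME or FIVE_PRIME
    grna_length: int = 20
    major_window: tuple[int, int] = (13, 17)
    minor_windows: tuple[tuple[int, int], ...] = ()
    context_rule: str | None = None  # required 5'-adjacent base, e.g. "T" for eA3A
    aliases: tuple[str, ...] = ()
    notes: str = ""

    @property
    def source_base(self) -> str:
        return self.conversion[0]

    @property
    def product_base(self) -> str:
        return self.conversion[2]

    def validate(self) -> None:
        if not self.name:
            raise EditorValidationError("name: must be non-empty")
        if self.conversion not in _CONVERSIONS:
            raise EditorValidationError(
                f"conversion: {self.conversion!r} is not one of {_CONVERSIONS}"
            )
        if self.pam_side not in _PAM_SIDES:
            raise EditorValidationError(
                f"pam_side: {self.pam_side!r} is not one of {_PAM_SIDES}"
            )
        if not self.pam:
            raise EditorValidationError("pam: must be non-empty")
        for ch in self.pam:
            if ch not in IUPAC_CODES:
                raise EditorValidationError(f"pam: {ch!r} is not an IUPAC code")
        if not isinstance(self.grna_length, int) or self.grna_length < 1:
            raise EditorValidationError(
                f"grna_length: must be a positive integer, got {self.grna_length!r}"
            )
        for label, window in [("major_window", self.major_window)] + [
            (f"minor_windows[{i}]", w) for i, w in enumerate(self.minor_windows)
        ]:
            lo, hi = window
            if not (1 <= lo <= hi <= self.grna_length):
                raise EditorValidationError(
                    f"{label}: [{lo}, {hi}] must satisfy 1 <= lo <= hi <= "
                    f"grna_length ({self.grna_length})"
                )
        mlo, mhi = self.major_window
        for i, (lo, hi) in enumerate(self.minor_windows):
            if lo <= mhi and mlo <= hi:
                raise EditorValidationError(
                    f"minor_windows[{i}]: [{lo}, {hi}] overlaps major_window "
                    f"[{mlo}, {mhi}]"
                )
        if self.context_rule is not None and self.context_rule not in "ACGT":
            raise EditorValidationError(
                f"context_rule: {self.context_rule!r} must be a single base A/C/G/T"
            )

    def in_major(self, distance: int) -> bool:
        lo, hi = self.major_window
        return lo <= distance <= hi

    def in_minor(self, distance: int) -> bool:
        return any(lo <= distance <= hi for lo, hi in self.minor_windows)

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "conversion": self.conversion,
            "pam": self.pam,
            "pam_side": self.pam_side,
            "grna_length": self.grna_length,
            "major_window": list(self.major_window),
            "minor_windows": [list(w) for w in self.minor_windows],
        }
        if self.context_rule:
            d["context_rule"] = self.context_rule
        if self.aliases:
            d["aliases"] = list(self.aliases)
        if self.notes:
            d["notes"] = self.notes
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BaseEditor":
        def window(value) -> tuple[int, int]:
            if isinstance(value, str):
                parts = value.replace("–", "-").split("-")
                if len(parts) == 1:
                    parts = parts * 2
                value = [int(p) for p in parts]
            lo, hi = value
            return int(lo), int(hi)

        try:
            name = str(d["name"])
            conversion = _normalize_conversion(str(d["conversion"]))
            pam = str(d["pam"]).upper()
            pam_side = _normalize_pam_side(str(d.get("pam_side", THREE_PRIME)))
            grna_length = int(d.get("grna_length", 20))
            major = window(d.get("major_window", d.get("major")))
        except (KeyError, TypeError, ValueError) as exc:
            raise EditorValidationError(f"malformed editor definition: {exc}") from exc
        minors_raw = d.get("minor_windows", d.get("minor", [])) or []
        if isinstance(minors_raw, str):
            minors_raw = [p for p in minors_raw.split(",") if p.strip()]
        minors = tuple(window(w) for w in minors_raw)
        context = d.get("context_rule") or None
        aliases = tuple(d.get("aliases", ()))
        editor = cls(
            name=name,
            conversion=conversion,
            pam=pam,
            pam_side=pam_side,
            grna_length=grna_length,
            major_window=major,
            minor_windows=minors,
            context_rule=context,
            aliases=aliases,
            notes=str(d.get("notes", "")),
        )
        editor.validate()
        return editor


class EditorRegistry:
    """Ordered collection of editors, unique by name, with alias lookup."""

    def __init__(self, editors: Iterable[BaseEditor] = ()) -> None:
        self._editors: dict[str, BaseEditor] = {}
        self._alias_map: dict[str, str] = {}
        for editor in editors:
            self.add(editor)

    def add(self, editor: BaseEditor) -> None:
        editor.validate()
        if editor.name in self._editors or editor.name in self._alias_map:
            raise EditorValidationError(f"name: duplicate editor name {editor.name!r}")
        for alias in editor.aliases:
            if alias in self._alias_map or alias in self._editors:
                raise EditorValidationError(f"aliases: duplicate alias {alias!r}")
        self._editors[editor.name] = editor
        for alias in editor.aliases:
            self._alias_map[alias] = editor.name

    def lookup(self, name: str) -> BaseEditor:
        """Resolve an editor by canonical name or alias."""
        if name in self._editors:
            return self._editors[name]
        if name in self._alias_map:
            return self._editors[self._alias_map[name]]
        raise KeyError(f"unknown editor {name!r}")

    def __contains__(self, name: str) -> bool:
        return name in self._editors or name in self._alias_map

    def __iter__(self) -> Iterator[BaseEditor]:
        return iter(self._editors.values())

    def __len__(self) -> int:
        return len(self._editors)

    def names(self) -> list[str]:
        return list(self._editors)

    def subset(self, names: Sequence[str]) -> "EditorRegistry":
        return EditorRegistry(self.lookup(n) for n in names)

    def merge(self, other: "EditorRegistry") -> "EditorRegistry":
        return EditorRegistry(list(self) + list(other))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EditorRegistry):
            return NotImplemented
        return list(self) == list(other)

    # --- serialization -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps([e.to_dict() for e in self], indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EditorRegistry":
        data = json.loads(text)
        if not isinstance(data, list):
            raise EditorValidationError("JSON editor file must be a list of objects")
        return cls(BaseEditor.from_dict(d) for d in data)

    _TSV_FIELDS = (
        "name",
        "conversion",
        "pam",
        "pam_side",
        "grna_length",
        "major_window",
        "minor_windows",
        "context_rule",
        "aliases",
        "notes",
    )

    def to_tsv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
        writer.writerow(self._TSV_FIELDS)
        for e in self:
            writer.writerow(
                [
                    e.name,
                    e.conversion,
                    e.pam,
                    e.pam_side,
                    e.grna_length,
                    f"{e.major_window[0]}-{e.major_window[1]}",
                    ",".join(f"{lo}-{hi}" for lo, hi in e.minor_windows) or ".",
                    e.context_rule or ".",
                    ",".join(e.aliases) or ".",
                    e.notes or ".",
                ]
            )
        return buf.getvalue()

    @classmethod
    def from_tsv(cls, text: str) -> "EditorRegistry":
        reader = csv.DictReader(io.StringIO(text), delimiter="\t")
        editors = []
        for row in reader:
            d = {k: v for k, v in row.items() if v not in (None, "", ".")}
            if "aliases" in d:
                d["aliases"] = d["aliases"].split(",")
            editors.append(BaseEditor.from_dict(d))
        return cls(editors)


def _be(name, conversion, major, minor=(), pam="NGG", pam_side=THREE_PRIME,
        grna_length=20, context=None, aliases=(), notes=""):
    return BaseEditor(
        name=name,
        conversion=conversion,
        pam=pam,
        pam_side=pam_side,
        grna_length=grna_length,
        major_window=major,
        minor_windows=tuple(minor),
        context_rule=context,
        aliases=tuple(aliases),
        notes=notes,
    )


# Published editors. Families whose constructs share every matching-relevant
# parameter (chemistry, PAM, windows, gRNA length) are one entry; the member
# construct names resolve through aliases.
_BUILTIN: tuple[BaseEditor, ...] = (
    _be(
        "BE1/BE2/BE3/HF-BE3/BE4(max)/BE4-Gam",
        "C>T",
        (13, 17),
        [(10, 12), (18, 19)],
        aliases=("BE1", "BE2", "BE3", "HF-BE3", "BE4", "BE4max", "BE4(max)", "BE4-Gam"),
    ),
    _be("YE1-BE3", "C>T", (14, 16), [(17, 17)]),
    _be("YEE-BE3", "C>T", (15, 15), [(16, 16)]),
    _be("VQR-BE3", "C>T", (10, 17), pam="NGAN"),
    _be("VRER-BE3", "C>T", (11, 18), pam="NGCG"),
    _be(
        "SaBE3/SaBE4/SaBE4-Gam",
        "C>T",
        (10, 19),
        pam="NNGRRT",
        grna_length=21,
        aliases=("SaBE3", "SaBE4", "SaBE4-Gam"),
    ),
    _be("Sa(KKH)-BE3", "C>T", (10, 19), pam="NNNRRT", grna_length=21),
    _be(
        "Cas12a-BE",
        "C>T",
        (10, 12),
        [(8, 9), (13, 13)],
        pam="TTTV",
        pam_side=FIVE_PRIME,
        notes="type V Cas; windows counted from the PAM into the protospacer",
    ),
    _be("Target-AID", "C>T", (17, 19), [(13, 16)]),
    _be("Target-AID-NG", "C>T", (17, 19), [(13, 16)], pam="NG"),
    _be("xBE3", "C>T", (13, 17), [(10, 12), (18, 19)], pam="NG"),
    _be(
        "eA3A-BE3",
        "C>T",
        (13, 17),
        [(10, 12), (18, 19)],
        context="T",
        notes="converts C only in a TC context (preceding base T)",
    ),
    _be("BE-PLUS", "C>T", (7, 17), [(5, 6)]),
    _be(
        "CP-CBEmax variants",
        "C>T",
        (12, 17),
        [(10, 11)],
        aliases=("CP-CBEmax",),
        notes="may exhibit editing upstream to the protospacer (not modeled)",
    ),
    _be("evoAPOBEC1-BE4max", "C>T", (13, 18), [(19, 20), (9, 12)]),
    _be("evoFERNY-BE4max", "C>T", (13, 18), [(19, 20)]),
    _be(
        "evoCDA1-BE4max",
        "C>T",
        (9, 20),
        [(7, 8)],
        notes="may exhibit editing upstream to the protospacer (not modeled)",
    ),
    _be("ABE 7.9", "A>G", (13, 16), [(12, 12), (17, 17)]),
    _be("ABE 7.10", "A>G", (14, 17), [(13, 13)]),
    _be("ABE 7.10*", "A>G", (13, 17), [(12, 12), (18, 19)]),
    _be(
        "xABE/NG-ABEmax",
        "A>G",
        (14, 17),
        [(13, 13)],
        pam="NG",
        aliases=("xABE", "NG-ABEmax"),
    ),
    _be("ABESa", "A>G", (10, 16), pam="NNGRRT", grna_length=21),
    _be("Sa(KKH)-ABE", "A>G", (10, 16), pam="NGA", grna_length=21),
    _be("VRER-ABE", "A>G", (15, 17), [(13, 14)], pam="NGCG"),
    _be("VQR-ABE", "A>G", (15, 17), [(13, 14)], pam="NNNRRT"),
    _be(
        "CP-ABEmax variants",
        "A>G",
        (14, 17),
        [(7, 13)],
        aliases=("CP-ABEmax",),
    ),
)


def builtin_registry() -> EditorRegistry:
    """The built-in repository: 26 published editors, 17 CBEs and 9 ABEs."""
    return EditorRegistry(_BUILTIN)


def load_custom_editors(source) -> EditorRegistry:
    """Load user-defined editors from a JSON or TSV document.

    ``source`` may be a path, a file-like object, a string of file content,
    or a list of dicts. JSON is a list of objects with the fields of
    :class:`BaseEditor`; TSV uses the same columns as ``EditorRegistry.to_tsv``.
    Every editor is validated; merging with the builtin registry is the
    caller's choice (see :meth:`EditorRegistry.merge`).
    """
    if isinstance(source, list):
        return EditorRegistry(BaseEditor.from_dict(d) for d in source)
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, (str, Path)) and Path(str(source)).exists() and (
        len(str(source)) < 4096
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    stripped = text.lstrip()
    if stripped.startswith("[") or stripped.startswith("{"):
        return EditorRegistry.from_json(text)
    return EditorRegistry.from_tsv(text)
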