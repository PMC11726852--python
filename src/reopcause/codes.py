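"""Semantics of NOMESCO procedure codes and ICD-10 diagnosis codes.

NOMESCO surgical codes are hierarchical strings such as ``KNGJ21``: chapter
``KN`` (musculoskeletal), anatomical region letter ``G`` (knee / lower leg)
at position 3, then the operation group and subcode.  Danish-dialect ICD-10
diagnosis codes keep a leading ``D`` and no dot (``DT846``).  Code *patterns*
are prefix templates, optionally with a region wildcard (``KNxU`` matches
``KNGU29`` for every region letter) or a contiguous range (``DT840``-``DT844``).
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field

#: The seven anatomical region letters used for extremity fracture surgery:
#: B=shoulder/upper arm, C=elbow/forearm, D=wrist/hand, E=pelvis,
#: F=hip/thigh, G=knee/lower leg, H=ankle/foot.
REGION_LETTERS = "BCDEFGH"

#: Surgical chapters considered when hunting for reoperations:
#: KA nervous system, KN musculoskeletal system, KQ skin.
SURGICAL_CHAPTERS = ("KA", "KN", "KQ")


class ConfigurationError(ValueError):
    """A code pattern or code-set configuration is malformed."""


class CodeKind(str, enum.Enum):
    PROCEDURE = "procedure"
    DIAGNOSIS = "diagnosis"


class Laterality(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    UNSPECIFIED = "unspecified"


def laterality_compatible(a: Laterality | str, b: Laterality | str) -> bool:
    """True unless both sides are specified and differ.

    A secondary procedure matches the index side when it was coded on the
    same side or carries no laterality coding at all; the relation is
    symmetric.
    """
    a = Laterality(a)
    b = Laterality(b)
    if Laterality.UNSPECIFIED in (a, b):
        return True
    return a == b


def infer_kind(text: str) -> CodeKind:
    if text.startswith("K"):
        return CodeKind.PROCEDURE
    if text.startswith("D"):
        return CodeKind.DIAGNOSIS
    raise ValueError(
        f"cannot infer code kind for {text!r}: procedure codes start with 'K',"
        " diagnosis codes with 'D'"
    )


@dataclass(frozen=True)
class Code:
    """One registry code, normalised to uppercase."""

    text: str
    kind: CodeKind

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("empty code")
        object.__setattr__(self, "text", self.text.strip().upper())
        object.__setattr__(self, "kind", CodeKind(self.kind))
        expected = infer_kind(self.text)
        if expected is not self.kind:
            raise ValueError(f"code {self.text!r} is not a {self.kind.value} code")

    @classmethod
    def parse(cls, text: str) -> "Code":
        text = text.strip().upper()
        return cls(text, infer_kind(text))


WILDCARD = "x"


def _validate_template(template: str, kind: CodeKind) -> str:
    """Uppercase a template, keeping the region wildcard as lowercase 'x'."""
    raw = template.strip()
    if not raw:
        raise ConfigurationError("empty pattern template")
    norm = "".join(
        WILDCARD if ch in ("x", "X") and i == 2 else ch.upper() for i, ch in enumerate(raw)
    )
    n_wild = sum(ch in ("x", "X") for ch in raw)
    if n_wild:
        if kind is not CodeKind.PROCEDURE or n_wild > 1 or norm[2] != WILDCARD or not norm.startswith("KN"):
            raise ConfigurationError(
                f"wildcard in {template!r} must appear exactly once, at the region"
                " position (position 3) of a 'KN' procedure template"
            )
    return norm


@dataclass(frozen=True)
class CodePattern:
    """A prefix template, optionally wildcarded or spanning a code range."""

    template: str
    kind: CodeKind
    range_end: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", CodeKind(self.kind))
        object.__setattr__(self, "template", _validate_template(self.template, self.kind))
        if self.range_end is not None:
            end = self.range_end.strip().upper()
            object.__setattr__(self, "range_end", end)
            if WILDCARD in self.template:
                raise ConfigurationError("range patterns cannot carry a wildcard")
            if len(end) != len(self.template):
                raise ConfigurationError(
                    f"range ends {self.template!r}..{end!r} differ in length"
                )
            if self.template > end:
                raise ConfigurationError(
                    f"range start {self.template!r} sorts after end {end!r}"
                )

    @classmethod
    def parse(cls, template: str, range_end: str | None = None, kind: str | None = None) -> "CodePattern":
        k = CodeKind(kind) if kind else infer_kind(template.strip().upper().replace("x", "X"))
        return cls(template, k, range_end)


def matches(pattern: CodePattern, code: Code) -> bool:
    """Prefix match of ``code`` against ``pattern``.

    The wildcard stands for any single region letter; a range pattern matches
    when the code's same-length prefix falls lexicographically inside
    ``[template, range_end]``.  Pattern and code must share a kind.
    """
    if pattern.kind is not code.kind:
        raise ValueError(
            f"kind mismatch: {pattern.template!r} is {pattern.kind.value},"
            f" {code.text!r} is {code.kind.value}"
        )
    text = code.text
    tpl = pattern.template
    if len(text) < len(tpl):
        return False
    if pattern.range_end is not None:
        prefix = text[: len(tpl)]
        return tpl <= prefix <= pattern.range_end
    for t_ch, c_ch in zip(tpl, text):
        if t_ch == WILDCARD:
            if c_ch not in REGION_LETTERS:
                return False
        elif t_ch != c_ch:
            return False
    return True


def any_match(patterns, code: Code) -> bool:
    """True if any same-kind pattern matches; other-kind patterns are skipped."""
    return any(p.kind is code.kind and matches(p, code) for p in patterns)


#: Per-chapter region policy. "pos3": the letter at position 3 names the
#: region when it is one of the seven region letters, otherwise the code is
#: region-neutral.  "neutral": the chapter never constrains the region.  A
#: single region letter pins the whole chapter to that region.
DEFAULT_CHAPTER_POLICY: dict[str, str] = {"KN": "pos3", "KQ": "pos3", "KA": "pos3"}


def region_of(code: Code | str, chapter_policy: dict[str, str] | None = None) -> str | None:
    """Anatomical region letter of a procedure code, or None if region-neutral.

    Diagnosis codes carry no region.  For ``KN`` codes the letter at position
    3 is authoritative; skin (KQ) and nerve (KA) chapters follow the
    configurable chapter policy, defaulting to the same positional rule with
    a region-neutral fallback.
    """
    if isinstance(code, str):
        code = Code.parse(code)
    if code.kind is CodeKind.DIAGNOSIS:
        return None
    policy = dict(DEFAULT_CHAPTER_POLICY)
    if chapter_policy:
        policy.update(chapter_policy)
    chapter = code.text[:2]
    rule = policy.get(chapter, "pos3")
    if rule == "neutral":
        return None
    if rule in REGION_LETTERS and len(rule) == 1:
        return rule
    if len(code.text) >= 3 and code.text[2] in REGION_LETTERS:
        return code.text[2]
    return None


def chapter_of(code: Code | str) -> str:
    text = code.text if isinstance(code, Code) else code.strip().upper()
    return text[:2]
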