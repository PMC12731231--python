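"""HLA allele nomenclature: parsing, validation, and two-field reduction.

HLA alleles follow the colon-delimited WHO nomenclature, e.g.
``HLA-A*02:01:01:01``: a locus symbol, then up to four numeric fields
(allele group, specific protein, synonymous coding change, non-coding
change), optionally followed by a one-letter expression suffix
(N = null, L = low, S = secreted, C = cytoplasmic, A = aberrant,
Q = questionable).  Two-field resolution (``A*02:01``) identifies a
distinct protein sequence and is the resolution at which genotypes are
compared throughout this package.

Field codes are stored as the digit text found in the input (leading
zeros preserved for display) but compared by numeric value, because
typing tools differ in zero-padding.  Gene symbols are uppercased and
the ``HLA-`` prefix is stripped on parse.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import InvalidAlleleError

EXPRESSION_SUFFIXES = frozenset("NLSCAQ")

#: Tokens that typing tools emit to mean "no call was made".
NO_CALL_TOKENS = frozenset({"no", "-", "", "na", "n/a", "none", "not typed", "nocall"})

_ALLELE_RE = re.compile(
    r"""^
    (?:HLA[-_])?                 # optional HLA- prefix
    (?P<gene>[A-Z]+[0-9]*)       # locus symbol, e.g. A, B, C, DRB1, DPA1
    \*
    (?P<fields>\d+(?::\d+){0,3}) # 1-4 colon-separated numeric fields
    (?P<suffix>[NLSCAQ])?        # optional expression suffix
    $""",
    re.VERBOSE | re.IGNORECASE,
)


@dataclass(frozen=True)
class AlleleName:
    """A parsed HLA allele identifier.

    Equality and hashing compare the gene (case-insensitively, already
    uppercased at construction), the numeric value of each field, and
    the expression suffix; ``raw`` and zero-padding are ignored.
    """

    gene: str
    fields: tuple[str, ...]
    expression_suffix: str = ""
    raw: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.gene:
            raise InvalidAlleleError(self.raw or "<empty>", "empty gene symbol")
        if not 1 <= len(self.fields) <= 4:
            raise InvalidAlleleError(self.raw or str(self.fields), "need 1-4 fields")
        for f in self.fields:
            if not f.isdigit():
                raise InvalidAlleleError(self.raw or f, f"non-numeric field {f!r}")
        if self.expression_suffix and self.expression_suffix not in EXPRESSION_SUFFIXES:
            raise InvalidAlleleError(self.raw, f"bad suffix {self.expression_suffix!r}")

    # -- equality on numeric field values, not padded text ---------------
    @property
    def _key(self) -> tuple:
        return (self.gene, tuple(int(f) for f in self.fields), self.expression_suffix)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleName):
            return NotImplemented
        return self._key == other._key

    def __hash__(self) -> int:
        return hash(self._key)

    def __lt__(self, other: "AlleleName") -> bool:
        return self._key < other._key

    def render(self, prefix: bool = False) -> str:
        """Canonical rendering ``GENE*FF:FF[suffix]``, e.g. ``A*02:01``.

        With ``prefix=True`` the ``HLA-`` prefix is re-added for export.
        """
        name = f"{self.gene}*{':'.join(self.fields)}{self.expression_suffix}"
        return f"HLA-{name}" if prefix else name

    def __str__(self) -> str:
        return self.render()

    @property
    def is_under_resolved(self) -> bool:
        """True for one-field names, which cannot identify a protein."""
        return len(self.fields) < 2


def parse_allele(text: str, dialect: str = "generic") -> AlleleName | None:
    """Parse HLA allele text into an :class:`AlleleName`.

    Accepts forms with or without the ``HLA-`` prefix.  ``dialect``
    controls tolerance for tool-specific decoration:

    * ``"seq2hla"`` — trailing ambiguity apostrophes (``A*02:01'``) are
      stripped; the caller is responsible for down-grading confidence.
    * ``"generic"`` (default) — strict canonical form.

    Returns ``None`` for a recognized no-call token (``no``, ``-``,
    ``NA`` ...); this is a distinct signal, not an error.  Raises
    :class:`~hlaensemble.errors.InvalidAlleleError` for text with no
    recognizable gene/field structure.
    """
    stripped = text.strip()
    if stripped.lower() in NO_CALL_TOKENS:
        return None
    candidate = stripped
    if dialect == "seq2hla":
        candidate = candidate.rstrip("'")
        if candidate.lower() in NO_CALL_TOKENS:
            return None
    m = _ALLELE_RE.match(candidate)
    if m is None:
        raise InvalidAlleleError(text)
    return AlleleName(
        gene=m.group("gene").upper(),
        fields=tuple(m.group("fields").split(":")),
        expression_suffix=(m.group("suffix") or "").upper(),
        raw=text,
    )


def to_two_field(a: AlleleName) -> AlleleName:
    """Reduce an allele name to two-field (protein-level) resolution.

    Gene and expression suffix are preserved: a null allele (suffix N)
    is functionally distinct from its expressed namesake even at the
    protein level, so the suffix participates in equality.  Idempotent;
    a one-field input is returned unchanged (it remains
    ``is_under_resolved``).
    """
    if len(a.fields) <= 2:
        return a
    return AlleleName(
        gene=a.gene,
        fields=a.fields[:2],
        expression_suffix=a.expression_suffix,
        raw=a.raw,
    )
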