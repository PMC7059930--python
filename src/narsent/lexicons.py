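"""Sentiment and verb-abstraction (LCM) lexicons.

Both lexicons are plain UTF-8 TSV tables keyed by lemma. Lookups are
case-insensitive: lemmas are lower-cased on load and on lookup.

The LCM lexicon has three tiers, consulted in this order during
annotation: sense-level entries (lemma + sense id), curated lemma-level
entries, and an automatically inferred default tier.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from .errors import LexiconError

PathLike = Union[str, Path]


class Polarity(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


class LCMClass(str, enum.Enum):
    """Verb abstraction classes, ordered from concrete to abstract."""

    DAV = "DAV"  # descriptive action verb
    IAV = "IAV"  # interpretative action verb
    SV = "SV"  # state verb


#: Abstraction weight of each verb class.
LCM_WEIGHTS = {LCMClass.DAV: 1, LCMClass.IAV: 2, LCMClass.SV: 3}


@dataclass
class SentimentLexicon:
    """Lemma -> polarity mapping."""

    entries: dict[str, Polarity] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lemma in self.entries:
            if not lemma:
                raise LexiconError("empty lemma in sentiment lexicon")
        self.entries = {k.lower(): v for k, v in self.entries.items()}

    def lookup(self, lemma: str) -> Optional[Polarity]:
        return self.entries.get(lemma.lower())

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, lemma: str) -> bool:
        return lemma.lower() in self.entries

    @property
    def positive_count(self) -> int:
        return sum(1 for p in self.entries.values() if p is Polarity.POSITIVE)

    @property
    def negative_count(self) -> int:
        return sum(1 for p in self.entries.values() if p is Polarity.NEGATIVE)


@dataclass
class LCMLexicon:
    """Three-tier verb classification lexicon.

    ``sense_entries`` maps ``(lemma, sense_id)`` pairs, ``lemma_entries``
    and ``default_entries`` map bare lemmas. Tiers may overlap; the
    resolution order (sense, lemma, default) is applied by the annotator.
    """

    sense_entries: dict[tuple[str, str], LCMClass] = field(default_factory=dict)
    lemma_entries: dict[str, LCMClass] = field(default_factory=dict)
    default_entries: dict[str, LCMClass] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sense_entries = {
            (l.lower(), s): c for (l, s), c in self.sense_entries.items()
        }
        self.lemma_entries = {l.lower(): c for l, c in self.lemma_entries.items()}
        self.default_entries = {l.lower(): c for l, c in self.default_entries.items()}

    def lookup(
        self, lemma: str, sense_id: Optional[str] = None
    ) -> tuple[Optional[LCMClass], Optional[str]]:
        """Resolve a lemma to ``(class, tier_name)``; ``(None, None)`` on miss."""
        lemma = lemma.lower()
        if sense_id:
            cls = self.sense_entries.get((lemma, sense_id))
            if cls is not None:
                return cls, "sense"
        cls = self.lemma_entries.get(lemma)
        if cls is not None:
            return cls, "lemma"
        cls = self.default_entries.get(lemma)
        if cls is not None:
            return cls, "default"
        return None, None

    def iav_lemmas(self) -> set[str]:
        lemmas = {l for (l, _), c in self.sense_entries.items() if c is LCMClass.IAV}
        lemmas |= {l for l, c in self.lemma_entries.items() if c is LCMClass.IAV}
        lemmas |= {l for l, c in self.default_entries.items() if c is LCMClass.IAV}
        return lemmas


def _read_tsv_rows(path: PathLike, n_cols: int) -> Iterable[list[str]]:
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != n_cols:
                raise LexiconError(
                    f"{path}:{lineno}: expected {n_cols} tab-separated fields, "
                    f"got {len(fields)}"
                )
            yield [f.strip() for f in fields]


def _parse_polarity(label: str, where: str) -> Polarity:
    try:
        return Polarity(label.lower())
    except ValueError:
        raise LexiconError(f"{where}: unknown polarity label {label!r}") from None


def _parse_lcm_class(label: str, where: str) -> LCMClass:
    try:
        return LCMClass(label.upper())
    except ValueError:
        raise LexiconError(
            f"{where}: LCM class must be one of DAV/IAV/SV, got {label!r}"
        ) from None


def load_sentiment_lexicon(path: PathLike) -> SentimentLexicon:
    """Load a two-column TSV (lemma, polarity).

    Duplicate rows with the same polarity are tolerated; a lemma listed
    with conflicting polarities raises :class:`LexiconError`.
    """
    entries: dict[str, Polarity] = {}
    for lemma, label in _read_tsv_rows(path, 2):
        lemma = lemma.lower()
        if not lemma:
            raise LexiconError(f"{path}: empty lemma")
        polarity = _parse_polarity(label, str(path))
        if lemma in entries and entries[lemma] is not polarity:
            raise LexiconError(
                f"{path}: lemma {lemma!r} listed with conflicting polarities"
            )
        entries[lemma] = polarity
    return SentimentLexicon(entries)


def load_lcm_lexicon(
    sense_path: Optional[PathLike] = None,
    lemma_path: Optional[PathLike] = None,
    default_path: Optional[PathLike] = None,
) -> LCMLexicon:
    """Load the three LCM tiers.

    Any tier path may be ``None`` (the tier is then simply absent).
    Sense tier rows are ``lemma<TAB>sense_id<TAB>class``; lemma and
    default tiers are ``lemma<TAB>class``.
    """
    sense: dict[tuple[str, str], LCMClass] = {}
    if sense_path is not None:
        for lemma, sense_id, label in _read_tsv_rows(sense_path, 3):
            sense[(lemma.lower(), sense_id)] = _parse_lcm_class(label, str(sense_path))
    lemma_tier: dict[str, LCMClass] = {}
    if lemma_path is not None:
        for lemma, label in _read_tsv_rows(lemma_path, 2):
            lemma_tier[lemma.lower()] = _parse_lcm_class(label, str(lemma_path))
    default_tier: dict[str, LCMClass] = {}
    if default_path is not None:
        for lemma, label in _read_tsv_rows(default_path, 2):
            default_tier[lemma.lower()] = _parse_lcm_class(label, str(default_path))
    return LCMLexicon(sense, lemma_tier, default_tier)


@dataclass
class LexiconReport:
    """Cross-lexicon consistency report (informational only)."""

    sentiment_size: int
    positive_count: int
    negative_count: int
    lcm_sense_size: int
    lcm_lemma_size: int
    lcm_default_size: int
    overlap_lemmas: int  # lemmas present in both lexicons
    warnings: list[str] = field(default_factory=list)


def validate_lexicons(
    sentiment: SentimentLexicon, lcm: LCMLexicon
) -> LexiconReport:
    """Report overlap statistics and IAV lemmas lacking a sentiment entry.

    Interpretative action verbs carry an evaluative component, so an IAV
    with no sentiment polarity is flagged (warning, never an error).
    """
    lcm_lemmas = (
        {l for l, _ in lcm.sense_entries}
        | set(lcm.lemma_entries)
        | set(lcm.default_entries)
    )
    overlap = lcm_lemmas & set(sentiment.entries)
    warnings = [
        f"IAV lemma {lemma!r} has no sentiment polarity"
        for lemma in sorted(lcm.iav_lemmas())
        if lemma not in sentiment
    ]
    return LexiconReport(
        sentiment_size=len(sentiment),
        positive_count=sentiment.positive_count,
        negative_count=sentiment.negative_count,
        lcm_sense_size=len(lcm.sense_entries),
        lcm_lemma_size=len(lcm.lemma_entries),
        lcm_default_size=len(lcm.default_entries),
        overlap_lemmas=len(overlap),
        warnings=warnings,
    )
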