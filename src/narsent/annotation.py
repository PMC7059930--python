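"""Per-token annotation: interpretation selection, sentiment and LCM labels.

Morphological analysis and contextual disambiguation happen upstream;
this module consumes their output — tokens carrying a lemma, a
colon-separated positional morphosyntactic tag and an interpretation
probability — picks one interpretation per surface form and attaches
dictionary labels.

Sentiment is a lemma lookup open to every part of speech. LCM classes
apply to verbal tokens only, resolved through the lexicon's three tiers:
sense entries first (when the token carries a sense id), then curated
lemma entries, then the automatically inferred default tier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .errors import ValidationError
from .lexicons import LCMClass, LCMLexicon, Polarity, SentimentLexicon

#: Tag of punctuation tokens in the positional tagset.
PUNCT_TAG = "interp"

#: Grammatical classes treated as verbal, i.e. eligible for LCM labels.
#: Covers finite forms, the l-participle, infinitive, imperative,
#: impersonals, future/modal auxiliaries and the predicative class.
DEFAULT_VERBAL_CLASSES = frozenset(
    {"fin", "praet", "inf", "impt", "imps", "bedzie", "winien", "pred"}
)


@dataclass(frozen=True)
class Token:
    """One token with its selected morphosyntactic interpretation."""

    surface: str
    lemma: str
    msd_tag: str
    probability: float = 1.0
    sense_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValidationError("token surface must be non-empty")
        if not self.msd_tag:
            raise ValidationError(f"token {self.surface!r}: msd_tag must be non-empty")
        if not 0.0 <= self.probability <= 1.0:
            raise ValidationError(
                f"token {self.surface!r}: probability {self.probability} "
                "outside [0, 1]"
            )

    @property
    def grammatical_class(self) -> str:
        """First field of the positional tag."""
        return self.msd_tag.split(":", 1)[0]

    @property
    def is_punct(self) -> bool:
        return self.grammatical_class == PUNCT_TAG


@dataclass(frozen=True)
class AnnotatedToken:
    """A token plus its sentiment polarity and LCM class (if any)."""

    token: Token
    sentiment: Optional[Polarity] = None
    lcm: Optional[LCMClass] = None
    lcm_tier: Optional[str] = None  # "sense" | "lemma" | "default"


def verbal_class(msd_tag: str, verbal_classes: frozenset[str] = DEFAULT_VERBAL_CLASSES) -> bool:
    """True iff the tag's grammatical class (first field) is verbal."""
    if not msd_tag:
        raise ValidationError("empty msd_tag")
    return msd_tag.split(":", 1)[0] in verbal_classes


def select_interpretation(candidates: Sequence[Token]) -> Token:
    """Pick the interpretation of maximal probability.

    Ties are broken deterministically by the lexicographically smallest
    ``(lemma, msd_tag)`` pair.
    """
    if not candidates:
        raise ValidationError("no candidate interpretations")
    return min(candidates, key=lambda t: (-t.probability, t.lemma, t.msd_tag))


def annotate_token(
    token: Token,
    sentiment_lexicon: SentimentLexicon,
    lcm_lexicon: LCMLexicon,
    verbal_classes: frozenset[str] = DEFAULT_VERBAL_CLASSES,
) -> AnnotatedToken:
    if token.is_punct:
        return AnnotatedToken(token)
    sentiment = sentiment_lexicon.lookup(token.lemma)
    lcm: Optional[LCMClass] = None
    tier: Optional[str] = None
    if verbal_class(token.msd_tag, verbal_classes):
        lcm, tier = lcm_lexicon.lookup(token.lemma, token.sense_id)
    return AnnotatedToken(token, sentiment=sentiment, lcm=lcm, lcm_tier=tier)


def annotate(
    tokens: Iterable[Token],
    sentiment_lexicon: SentimentLexicon,
    lcm_lexicon: LCMLexicon,
    verbal_classes: frozenset[str] = DEFAULT_VERBAL_CLASSES,
) -> list[AnnotatedToken]:
    """Annotate a flat token sequence. Unknown lemmas stay unlabeled."""
    return [
        annotate_token(t, sentiment_lexicon, lcm_lexicon, verbal_classes)
        for t in tokens
    ]


def annotate_utterances(
    utterances: Sequence[Sequence[Token]],
    sentiment_lexicon: SentimentLexicon,
    lcm_lexicon: LCMLexicon,
    verbal_classes: frozenset[str] = DEFAULT_VERBAL_CLASSES,
) -> list[list[AnnotatedToken]]:
    """Annotate utterance-grouped tokens, preserving the grouping."""
    return [
        annotate(utt, sentiment_lexicon, lcm_lexicon, verbal_classes)
        for utt in utterances
    ]
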