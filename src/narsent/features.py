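"""Per-participant feature aggregation.

Each participant x task sample is reduced to one feature vector: token
and utterance counts, mean length of utterance, sentiment counts, verb
abstraction-class counts, the weighted abstraction score, and a
morphosyntactic frequency profile.

Counts are raw (not length-normalised). MLU is the participant-level
ratio total tokens / total utterances. Punctuation is excluded from
``n_tokens`` and from all morphosyntactic counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .annotation import AnnotatedToken
from .errors import ValidationError
from .lexicons import LCM_WEIGHTS, LCMClass, Polarity
from .transcripts_io import Group, Task

#: Grammatical classes of the positional tagset (punctuation excluded).
MSD_CLASSES = [
    "adj", "adja", "adjc", "adjp", "adv", "aglt", "bedzie", "brev", "burk",
    "comp", "conj", "depr", "fin", "ger", "imps", "impt", "inf", "interj",
    "num", "numcol", "pact", "pant", "pcon", "ppas", "ppron12", "ppron3",
    "praet", "pred", "prep", "qub", "siebie", "subst", "winien", "xxx",
]

#: Inflectional category marginals counted across all word tokens.
#: A dotted tag value (e.g. ``nom.acc``) contributes to every listed value.
MSD_CATEGORIES: dict[str, list[str]] = {
    "case": ["nom", "gen", "dat", "acc", "inst", "loc", "voc"],
    "number": ["sg", "pl"],
    "gender": ["m1", "m2", "m3", "f", "n"],
    "person": ["pri", "sec", "ter"],
    "degree": ["pos", "com", "sup"],
    "aspect": ["imperf", "perf"],
}


def msd_keys(categories: Optional[Mapping[str, list[str]]] = None) -> list[str]:
    """The full ordered key manifest of the morphosyntactic profile."""
    categories = MSD_CATEGORIES if categories is None else categories
    keys = [f"class={c}" for c in MSD_CLASSES]
    for cat, values in categories.items():
        keys.extend(f"{cat}={v}" for v in values)
    return keys


@dataclass
class FeatureVector:
    participant_id: str
    group: Optional[Group]
    task: Optional[Task]
    n_tokens: int
    n_utterances: int
    mlu: float
    n_pos: int
    n_neg: int
    n_dav: int
    n_iav: int
    n_sv: int
    abstraction: int
    msd_freq: dict[str, int] = field(default_factory=dict)
    duration_s: Optional[float] = None


def abstraction_score(n_dav: int, n_iav: int, n_sv: int) -> int:
    """Weighted abstraction score: DAV + 2*IAV + 3*SV."""
    if n_dav < 0 or n_iav < 0 or n_sv < 0:
        raise ValidationError("verb-class counts must be non-negative")
    return n_dav + 2 * n_iav + 3 * n_sv


def _tag_values(msd_tag: str) -> set[str]:
    """All inflectional values of a tag, expanding dotted alternatives."""
    values: set[str] = set()
    for fld in msd_tag.split(":")[1:]:
        values.update(fld.split("."))
    return values


def extract_features(
    annotated: Sequence[Sequence[AnnotatedToken]],
    participant_id: str,
    group: Optional[Group] = None,
    task: Optional[Task] = None,
    duration_s: Optional[float] = None,
    categories: Optional[Mapping[str, list[str]]] = None,
) -> FeatureVector:
    """Aggregate annotated utterances into one feature vector."""
    if not annotated or all(not u for u in annotated):
        raise ValidationError(f"participant {participant_id!r}: empty transcript")
    categories = MSD_CATEGORIES if categories is None else categories

    n_tokens = 0
    n_utterances = 0
    n_pos = n_neg = 0
    lcm_counts = {LCMClass.DAV: 0, LCMClass.IAV: 0, LCMClass.SV: 0}
    freq: dict[str, int] = {k: 0 for k in msd_keys(categories)}

    for utt in annotated:
        if not utt:
            continue
        n_utterances += 1
        for at in utt:
            tok = at.token
            if tok.is_punct:
                continue
            n_tokens += 1
            if at.sentiment is Polarity.POSITIVE:
                n_pos += 1
            elif at.sentiment is Polarity.NEGATIVE:
                n_neg += 1
            if at.lcm is not None:
                lcm_counts[at.lcm] += 1
            cls_key = f"class={tok.grammatical_class}"
            if cls_key not in freq:
                freq[cls_key] = 0
            freq[cls_key] += 1
            values = _tag_values(tok.msd_tag)
            for cat, cat_values in categories.items():
                for v in cat_values:
                    if v in values:
                        freq[f"{cat}={v}"] += 1

    n_dav = lcm_counts[LCMClass.DAV]
    n_iav = lcm_counts[LCMClass.IAV]
    n_sv = lcm_counts[LCMClass.SV]
    return FeatureVector(
        participant_id=participant_id,
        group=group,
        task=task,
        n_tokens=n_tokens,
        n_utterances=n_utterances,
        mlu=n_tokens / n_utterances if n_utterances else 0.0,
        n_pos=n_pos,
        n_neg=n_neg,
        n_dav=n_dav,
        n_iav=n_iav,
        n_sv=n_sv,
        abstraction=abstraction_score(n_dav, n_iav, n_sv),
        msd_freq=freq,
        duration_s=duration_s,
    )


def per_token_abstraction(annotated: Iterable[AnnotatedToken]) -> int:
    """Independent per-token route to the abstraction score: sum of the
    class weights (1/2/3) over every LCM-labelled token."""
    return sum(LCM_WEIGHTS[at.lcm] for at in annotated if at.lcm is not None)


CORE_COLUMNS = [
    "participant_id", "group", "task", "duration_s", "n_tokens",
    "n_utterances", "mlu", "n_pos", "n_neg", "n_dav", "n_iav", "n_sv",
    "abstraction",
]


def feature_table(vectors: Iterable[FeatureVector]) -> pd.DataFrame:
    """One row per participant x task; msd_freq flattened to ``msd_*``."""
    rows = []
    seen: set[tuple[str, Optional[Task]]] = set()
    for v in vectors:
        key = (v.participant_id, v.task)
        if key in seen:
            raise ValidationError(
                f"duplicate feature row for {v.participant_id!r}, task {v.task}"
            )
        seen.add(key)
        row: dict = {
            "participant_id": v.participant_id,
            "group": v.group.value if v.group else "",
            "task": v.task.value if v.task else "",
            "duration_s": v.duration_s,
            "n_tokens": v.n_tokens,
            "n_utterances": v.n_utterances,
            "mlu": v.mlu,
            "n_pos": v.n_pos,
            "n_neg": v.n_neg,
            "n_dav": v.n_dav,
            "n_iav": v.n_iav,
            "n_sv": v.n_sv,
            "abstraction": v.abstraction,
        }
        for k, c in v.msd_freq.items():
            row[f"msd_{k}"] = c
        rows.append(row)
    if not rows:
        raise ValidationError("no feature vectors to tabulate")
    df = pd.DataFrame(rows)
    msd_cols = sorted(c for c in df.columns if c.startswith("msd_"))
    df[msd_cols] = df[msd_cols].fillna(0).astype(int)
    return df[CORE_COLUMNS + msd_cols]
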