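"""Transcript input/output: CHAT files, token tables, metadata.

CHAT support is a minimal, documented subset of the main-tier
conventions sufficient for narrative language samples:

* header lines start with ``@``; ``@ID`` rows populate participant
  metadata when their speaker code matches the target speaker;
* main tiers start with ``*XXX:``; a line starting with a tab continues
  the previous tier; ``%`` dependent tiers are ignored;
* cleaning (see :func:`clean_chat_tokens`): retracing/repetition markers
  ``[/]``, ``[//]``, ``[///]`` remove the single token or ``<...>``
  group they scope; other bracketed codes are dropped (their scoped
  material is kept); ``&=events``, pause codes ``(.)``/``(..)``/
  ``(...)``, fragments ``&+``, omissions ``0word`` and unintelligible
  ``xxx``/``yyy``/``www`` are dropped; fillers ``&-um`` are kept as
  plain tokens; ``@x`` form markers are stripped; terminators
  containing ``.``/``?``/``!`` are normalised to that mark, which is
  kept as a punctuation token.

The annotated-token-table dialect is fixed: UTF-8, tab-separated,
header row, columns ``utterance_index, surface, lemma, msd_tag,
probability, sense_id`` (plus ``sentiment, lcm`` once annotated).
Empty optional fields are written as empty strings, never ``"None"``.
"""

from __future__ import annotations

import csv
import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from .annotation import PUNCT_TAG, AnnotatedToken, Token
from .errors import ChatParseError, SchemaError, ValidationError
from .lexicons import LCMClass, Polarity

PathLike = Union[str, Path]

TOKEN_TABLE_COLUMNS = [
    "utterance_index",
    "surface",
    "lemma",
    "msd_tag",
    "probability",
    "sense_id",
]
ANNOTATED_COLUMNS = TOKEN_TABLE_COLUMNS + ["sentiment", "lcm"]


class Group(str, enum.Enum):
    ASD = "ASD"
    TD = "TD"


class Task(str, enum.Enum):
    BOOK = "book"
    PICTURE = "picture"


@dataclass
class Utterance:
    """One cleaned main tier."""

    speaker_code: str
    tokens: list[str]
    raw_line: str = ""

    def __post_init__(self) -> None:
        if any(not t for t in self.tokens):
            raise ValidationError("utterance contains empty token strings")


@dataclass
class Transcript:
    """One participant x task language sample."""

    participant_id: str
    utterances: list[Utterance]
    group: Optional[Group] = None
    task: Optional[Task] = None
    duration_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group is not None:
            self.group = Group(self.group)
        if self.task is not None:
            self.task = Task(self.task)
        if self.duration_s is not None and self.duration_s < 0:
            raise ValidationError("duration_s must be non-negative")


@dataclass
class Corpus:
    """A collection of transcripts, unique per (participant, task)."""

    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, Optional[Task]], None] = {}
        groups: dict[str, Optional[Group]] = {}
        for t in self.transcripts:
            key = (t.participant_id, t.task)
            if key in seen:
                raise ValidationError(
                    f"duplicate transcript for participant {t.participant_id!r}, "
                    f"task {t.task}"
                )
            seen[key] = None
            prev = groups.get(t.participant_id)
            if prev is not None and t.group is not None and prev != t.group:
                raise ValidationError(
                    f"participant {t.participant_id!r} appears in two groups"
                )
            if t.group is not None:
                groups[t.participant_id] = t.group

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts)


# --- CHAT parsing -----------------------------------------------------------

_ANGLE_RETRACE = re.compile(r"<[^<>]*>\s*\[/{1,3}\]")
_RETRACE_MARK = re.compile(r"^\[/{1,3}\]$")
_BRACKET_CODE = re.compile(r"\[[^\[\]]*\]")
_PAUSE = re.compile(r"\(\.{1,3}\)")

_TERMINATOR_MARKS = {".": ".", "?": "?", "!": "!"}


def _drop_bare_retraces(words: list[str]) -> list[str]:
    """Drop material scoped by an unbracketed retracing marker.

    The marker scopes the longest run of preceding words that is repeated
    immediately after it; with no repetition it scopes the single
    preceding word.
    """
    out: list[str] = []
    i = 0
    while i < len(words):
        w = words[i]
        if _RETRACE_MARK.match(w):
            rest = words[i + 1 :]
            k = 0
            for cand in range(min(len(out), len(rest)), 0, -1):
                if out[-cand:] == rest[:cand]:
                    k = cand
                    break
            del out[len(out) - max(k, 1) :]
        else:
            out.append(w)
        i += 1
    return out


def clean_chat_tokens(tier_text: str) -> list[str]:
    """Apply the documented CHAT cleaning rules to one main-tier text."""
    text = tier_text
    # angle-group retracing: drop scoped material together with the marker
    prev = None
    while prev != text:
        prev = text
        text = _ANGLE_RETRACE.sub(" ", text)
    text = " ".join(_drop_bare_retraces(text.split()))
    # remaining bracketed codes: drop marker, keep scoped material
    text = _BRACKET_CODE.sub(" ", text)
    text = _PAUSE.sub(" ", text)
    text = text.replace("<", " ").replace(">", " ")
    tokens: list[str] = []
    for raw in text.split():
        tok = raw
        if tok.startswith("&="):  # local events
            continue
        if tok.startswith("&+"):  # phonological fragments
            continue
        if tok.startswith("&-"):  # fillers kept as words
            tok = tok[2:]
        elif tok.startswith("&"):
            tok = tok[1:]
        if tok.startswith("+"):  # terminator / linking codes
            mark = next((m for m in _TERMINATOR_MARKS if m in tok), None)
            if mark:
                tokens.append(mark)
            continue
        if tok.startswith("0"):  # omitted words
            continue
        if "@" in tok:
            tok = tok.split("@", 1)[0]
        tok = tok.strip(",;:„”\"")
        if not tok:
            continue
        if tok in ("xxx", "yyy", "www"):
            continue
        tokens.append(tok)
    return tokens


_TIER_RE = re.compile(r"^\*([A-Za-z0-9]+):\s*(.*)$")


def read_chat(path: PathLike, target_speaker: str) -> Transcript:
    """Read a CHAT file, keeping only the target speaker's utterances.

    Raises :class:`ChatParseError` with the offending line number on
    malformed main tiers, and an error listing the available speaker
    codes when ``target_speaker`` never occurs.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not any(line.strip() for line in lines):
        raise ChatParseError(f"{path}: empty CHAT file")

    participant_id = path.stem
    group: Optional[Group] = None
    tiers: list[tuple[str, str]] = []  # (speaker, full tier text)
    seen_codes: list[str] = []

    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith("@"):
            if line.startswith("@ID:"):
                fields = [f.strip() for f in line[4:].split("|")]
                # @ID: language|corpus|code|age|sex|group|SES|role|...
                if len(fields) >= 3 and fields[2] == target_speaker:
                    if len(fields) >= 4 and fields[3]:
                        participant_id = fields[3] or participant_id
                    if len(fields) >= 6 and fields[5] in Group._value2member_map_:
                        group = Group(fields[5])
            continue
        if line.startswith("%"):
            continue
        if line.startswith(("\t", " ")):
            if not tiers:
                raise ChatParseError(
                    f"{path}:{lineno}: continuation line before any main tier"
                )
            spk, text = tiers[-1]
            tiers[-1] = (spk, text + " " + line.strip())
            continue
        if line.startswith("*"):
            m = _TIER_RE.match(line)
            if not m:
                raise ChatParseError(f"{path}:{lineno}: malformed main tier {line!r}")
            spk = m.group(1)
            if spk not in seen_codes:
                seen_codes.append(spk)
            tiers.append((spk, m.group(2)))
            continue
        raise ChatParseError(f"{path}:{lineno}: unrecognized line {line!r}")

    if target_speaker not in seen_codes:
        raise ChatParseError(
            f"{path}: speaker {target_speaker!r} not found; "
            f"available codes: {', '.join(seen_codes) or '(none)'}"
        )

    utterances = []
    for spk, text in tiers:
        if spk != target_speaker:
            continue
        tokens = clean_chat_tokens(text)
        if tokens:
            utterances.append(Utterance(spk, tokens, raw_line=text))
    return Transcript(participant_id=participant_id, utterances=utterances, group=group)


# --- token tables -----------------------------------------------------------


def _parse_probability(value: str, where: str) -> float:
    try:
        p = float(value)
    except ValueError:
        raise ValidationError(f"{where}: probability {value!r} is not a number") from None
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"{where}: probability {p} outside [0, 1]")
    return p


def read_token_table(path: PathLike) -> list[list[Token]]:
    """Read an annotated token table TSV, grouped into utterances."""
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty token table (no header)")
        missing = [c for c in TOKEN_TABLE_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required columns: {', '.join(missing)}")
        utterances: dict[int, list[Token]] = {}
        for lineno, row in enumerate(reader, start=2):
            where = f"{path}:{lineno}"
            try:
                idx = int(row["utterance_index"])
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{where}: utterance_index {row['utterance_index']!r} "
                    "is not an integer"
                ) from None
            token = Token(
                surface=row["surface"],
                lemma=row["lemma"],
                msd_tag=row["msd_tag"],
                probability=_parse_probability(row["probability"], where),
                sense_id=row["sense_id"] or None,
            )
            utterances.setdefault(idx, []).append(token)
    return [utterances[i] for i in sorted(utterances)]


def write_token_table(utterances: Sequence[Sequence[Token]], path: PathLike) -> None:
    """Write utterance-grouped tokens; inverse of :func:`read_token_table`."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TOKEN_TABLE_COLUMNS)
        for idx, utt in enumerate(utterances):
            for tok in utt:
                writer.writerow(
                    [
                        idx,
                        tok.surface,
                        tok.lemma,
                        tok.msd_tag,
                        _format_probability(tok.probability),
                        tok.sense_id or "",
                    ]
                )


def _format_probability(p: float) -> str:
    return repr(p) if p != int(p) else str(int(p)) + ".0"


def read_annotated_table(path: PathLike) -> list[list[AnnotatedToken]]:
    """Read a token table carrying ``sentiment`` and ``lcm`` columns."""
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty annotated table (no header)")
        missing = [c for c in ANNOTATED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required columns: {', '.join(missing)}")
        utterances: dict[int, list[AnnotatedToken]] = {}
        for lineno, row in enumerate(reader, start=2):
            where = f"{path}:{lineno}"
            idx = int(row["utterance_index"])
            token = Token(
                surface=row["surface"],
                lemma=row["lemma"],
                msd_tag=row["msd_tag"],
                probability=_parse_probability(row["probability"], where),
                sense_id=row["sense_id"] or None,
            )
            sentiment = Polarity(row["sentiment"]) if row["sentiment"] else None
            lcm = LCMClass(row["lcm"]) if row["lcm"] else None
            utterances.setdefault(idx, []).append(
                AnnotatedToken(token, sentiment=sentiment, lcm=lcm)
            )
    return [utterances[i] for i in sorted(utterances)]


def write_annotated_table(
    utterances: Sequence[Sequence[AnnotatedToken]], path: PathLike
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATED_COLUMNS)
        for idx, utt in enumerate(utterances):
            for at in utt:
                tok = at.token
                writer.writerow(
                    [
                        idx,
                        tok.surface,
                        tok.lemma,
                        tok.msd_tag,
                        _format_probability(tok.probability),
                        tok.sense_id or "",
                        at.sentiment.value if at.sentiment else "",
                        at.lcm.value if at.lcm else "",
                    ]
                )


# --- metadata ---------------------------------------------------------------


@dataclass(frozen=True)
class ParticipantMeta:
    participant_id: str
    group: Group
    task: Task
    duration_s: Optional[float] = None


def read_metadata(path: PathLike) -> list[ParticipantMeta]:
    """Read the participant metadata CSV.

    Columns: participant_id, group, task, duration_s (may be empty).
    """
    path = Path(path)
    required = ["participant_id", "group", "task", "duration_s"]
    out: list[ParticipantMeta] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty metadata file")
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required columns: {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            duration = row["duration_s"]
            try:
                group = Group(row["group"])
                task = Task(row["task"])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
            dur = float(duration) if duration not in (None, "") else None
            if dur is not None and dur < 0:
                raise ValidationError(f"{path}:{lineno}: negative duration_s")
            out.append(ParticipantMeta(row["participant_id"], group, task, dur))
    keys = [(m.participant_id, m.task) for m in out]
    if len(set(keys)) != len(keys):
        raise ValidationError(f"{path}: duplicate (participant_id, task) rows")
    return out


def write_metadata(meta: Sequence[ParticipantMeta], path: PathLike) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["participant_id", "group", "task", "duration_s"])
        for m in meta:
            writer.writerow(
                [
                    m.participant_id,
                    m.group.value,
                    m.task.value,
                    "" if m.duration_s is None else m.duration_s,
                ]
            )
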