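"""Synthetic corpora and feature tables.

Per-participant category counts (positive/negative sentiment words,
DAV/IAV/SV verbs, neutral fillers) are drawn from negative-binomial
distributions moment-matched to the published group summaries of the
book task; infinite dispersion degenerates to Poisson. The abstraction
score is always derived from the drawn verb-class counts, never
simulated directly.

``generate_corpus`` additionally realises the counts as token streams
over closed per-category vocabularies, so running the full annotation
and feature-extraction pipeline recovers the generating counts exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .lexicons import (
    LCMLexicon,
    SentimentLexicon,
    load_lcm_lexicon,
    load_sentiment_lexicon,
)
from .annotation import Token
from .transcripts_io import (
    Corpus,
    Group,
    ParticipantMeta,
    Task,
    Transcript,
    Utterance,
    write_metadata,
    write_token_table,
)

PathLike = Union[str, Path]

CATEGORIES = ["pos", "neg", "dav", "iav", "sv", "filler"]


@dataclass(frozen=True)
class CountParams:
    """Negative-binomial mean/dispersion; dispersion=inf means Poisson."""

    mean: float
    dispersion: float = math.inf

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValidationError("count mean must be >= 0")
        if not self.dispersion > 0:
            raise ValidationError("dispersion must be > 0")


def _moment_matched(mean: float, sd: float) -> CountParams:
    """NB params matching a printed mean/SD; Poisson if not overdispersed."""
    var = sd * sd
    if var <= mean:
        return CountParams(mean)
    return CountParams(mean, mean * mean / (var - mean))


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic corpus generator.

    ``rates`` maps (group, task) to per-category count parameters.
    ``missing_task_prob`` gives the probability that a participant's
    sample for a task is absent. ``utterance_mean_len`` controls how
    tokens are partitioned into utterances.
    """

    n_per_group: int = 25
    rates: dict[tuple[str, str], dict[str, CountParams]] = field(default_factory=dict)
    utterance_mean_len: float = 9.0
    missing_task_prob: dict[str, float] = field(
        default_factory=lambda: {"book": 0.0, "picture": 0.0}
    )
    duration_mean_s: float = 150.0
    duration_sd_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValidationError("n_per_group must be >= 1")
        if self.utterance_mean_len < 1:
            raise ValidationError("utterance_mean_len must be >= 1")
        for task, p in self.missing_task_prob.items():
            Task(task)
            if not 0.0 <= p <= 1.0:
                raise ValidationError("missing_task_prob must be in [0, 1]")
        for (g, t), cats in self.rates.items():
            Group(g), Task(t)
            for c in cats:
                if c not in CATEGORIES:
                    raise ValidationError(f"unknown category {c!r}")

    @property
    def tasks(self) -> list[str]:
        return sorted({t for _, t in self.rates})

    @classmethod
    def from_yaml(cls, path: PathLike) -> "GeneratorConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        rates = {}
        for key, cats in (raw.pop("rates", None) or {}).items():
            g, t = key.split("/")
            rates[(g, t)] = {
                c: CountParams(
                    float(v["mean"]),
                    float(v.get("dispersion", math.inf)),
                )
                for c, v in cats.items()
            }
        return cls(rates=rates, **raw)


def default_config(seed: int = 0, n_per_group: int = 25) -> GeneratorConfig:
    """Defaults moment-matched to the published book-task group summaries.

    IAV means are chosen so each group's expected abstraction score
    matches its published mean given the published DAV/SV means. The
    picture task uses attenuated rates (no group effect), matching the
    published pattern of book-task-only differences.
    """
    book = {
        "ASD": {
            "pos": _moment_matched(0.84, 0.75),
            "neg": _moment_matched(1.08, 1.38),
            "dav": _moment_matched(13.24, 7.48),
            # (68.24 - 13.24 - 3*13.00) / 2
            "iav": _moment_matched(8.0, 4.0),
            "sv": _moment_matched(13.00, 7.35),
            "filler": _moment_matched(120.0, 40.0),
        },
        "TD": {
            "pos": _moment_matched(2.28, 2.41),
            "neg": _moment_matched(2.32, 2.78),
            "dav": _moment_matched(18.48, 8.48),
            # (94.12 - 18.48 - 3*18.36) / 2
            "iav": _moment_matched(10.28, 5.0),
            "sv": _moment_matched(18.36, 10.04),
            "filler": _moment_matched(130.0, 40.0),
        },
    }
    picture = {
        g: {
            "pos": _moment_matched(1.5, 1.8),
            "neg": _moment_matched(0.6, 1.0),
            "dav": _moment_matched(7.0, 4.0),
            "iav": _moment_matched(4.0, 3.0),
            "sv": _moment_matched(6.0, 4.0),
            "filler": _moment_matched(80.0, 30.0),
        }
        for g in ("ASD", "TD")
    }
    rates = {}
    for g in ("ASD", "TD"):
        rates[(g, "book")] = book[g]
        rates[(g, "picture")] = picture[g]
    return GeneratorConfig(
        n_per_group=n_per_group,
        rates=rates,
        missing_task_prob={"book": 0.0, "picture": 0.22},
        seed=seed,
    )


def _draw_count(rng: np.random.Generator, params: CountParams) -> int:
    if params.mean == 0:
        return 0
    if math.isinf(params.dispersion):
        return int(rng.poisson(params.mean))
    k = params.dispersion
    return int(rng.negative_binomial(k, k / (k + params.mean)))


def _draw_rows(config: GeneratorConfig, rng: np.random.Generator):
    """Yield (participant_id, group, task, counts dict, duration)."""
    for group in ("ASD", "TD"):
        for i in range(config.n_per_group):
            pid = f"{group}{i + 1:03d}"
            for task in config.tasks:
                if rng.random() < config.missing_task_prob.get(task, 0.0):
                    continue
                params = config.rates[(group, task)]
                counts = {
                    c: _draw_count(rng, params[c]) if c in params else 0
                    for c in CATEGORIES
                }
                duration = max(
                    1.0, rng.normal(config.duration_mean_s, config.duration_sd_s)
                )
                yield pid, group, task, counts, duration


def generate_feature_table(
    config: GeneratorConfig, seed: Optional[int] = None
) -> pd.DataFrame:
    """Draw per-participant category counts into a core feature table.

    The abstraction column is recomputed from the drawn DAV/IAV/SV
    counts. Deterministic for a fixed seed.
    """
    if not config.rates:
        raise ValidationError("config has no rate parameters")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    for pid, group, task, counts, duration in _draw_rows(config, rng):
        n_tokens = sum(counts.values())
        n_utts = max(1, round(n_tokens / config.utterance_mean_len))
        rows.append(
            {
                "participant_id": pid,
                "group": group,
                "task": task,
                "duration_s": round(duration, 1),
                "n_tokens": n_tokens,
                "n_utterances": n_utts,
                "mlu": n_tokens / n_utts,
                "n_pos": counts["pos"],
                "n_neg": counts["neg"],
                "n_dav": counts["dav"],
                "n_iav": counts["iav"],
                "n_sv": counts["sv"],
                "abstraction": counts["dav"] + 2 * counts["iav"] + 3 * counts["sv"],
            }
        )
    return pd.DataFrame(rows)


# --- token-level generation ---------------------------------------------------


@dataclass(frozen=True)
class Vocabulary:
    """Closed per-category lemma pools with fixed morphosyntactic tags."""

    positive: tuple[str, ...]
    negative: tuple[str, ...]
    dav: tuple[str, ...]
    iav: tuple[str, ...]
    sv: tuple[str, ...]
    filler: tuple[str, ...]

    def pool(self, category: str) -> tuple[str, ...]:
        return {
            "pos": self.positive,
            "neg": self.negative,
            "dav": self.dav,
            "iav": self.iav,
            "sv": self.sv,
            "filler": self.filler,
        }[category]


_CATEGORY_TAGS = {
    "pos": "adj:sg:nom:m1:pos",
    "neg": "adj:sg:nom:m1:pos",
    "dav": "fin:sg:ter:imperf",
    "iav": "fin:sg:ter:imperf",
    "sv": "fin:sg:ter:imperf",
    "filler": "subst:sg:nom:m3",
}


def _data_path(name: str) -> Path:
    return Path(resources.files("narsent").joinpath("data", name))  # type: ignore[arg-type]


def toy_vocabulary() -> Vocabulary:
    """Toy Polish-like vocabulary aligned with the shipped toy lexicons."""
    sent = load_sentiment_lexicon(_data_path("toy_sentiment.tsv"))
    lcm = load_lcm_lexicon(lemma_path=_data_path("toy_lcm_lemma.tsv"))
    pos = tuple(sorted(l for l, p in sent.entries.items() if p.value == "positive"))
    neg = tuple(sorted(l for l, p in sent.entries.items() if p.value == "negative"))
    by_class = {"DAV": [], "IAV": [], "SV": []}
    for lemma, cls in sorted(lcm.lemma_entries.items()):
        by_class[cls.value].append(lemma)
    return Vocabulary(
        positive=pos,
        negative=neg,
        dav=tuple(by_class["DAV"]),
        iav=tuple(by_class["IAV"]),
        sv=tuple(by_class["SV"]),
        filler=("nastrój", "żaba", "dom", "drzewo", "woda", "miasto", "liść", "noc"),
    )


def toy_lexicons() -> tuple[SentimentLexicon, LCMLexicon]:
    """The shipped toy sentiment and three-tier LCM lexicons."""
    sentiment = load_sentiment_lexicon(_data_path("toy_sentiment.tsv"))
    lcm = load_lcm_lexicon(
        sense_path=_data_path("toy_lcm_sense.tsv"),
        lemma_path=_data_path("toy_lcm_lemma.tsv"),
        default_path=_data_path("toy_lcm_default.tsv"),
    )
    return sentiment, lcm


@dataclass
class SyntheticCorpus:
    corpus: Corpus
    token_tables: dict[tuple[str, str], list[list[Token]]]  # (pid, task) -> utterances
    metadata: list[ParticipantMeta]
    truth: pd.DataFrame  # generating counts, one row per participant x task


def generate_corpus(
    config: GeneratorConfig,
    vocabulary: Optional[Vocabulary] = None,
    seed: Optional[int] = None,
) -> SyntheticCorpus:
    """Realise drawn counts as utterance-grouped token streams.

    Category vocabularies are closed and disjoint, so annotating the
    emitted token tables with the toy lexicons and extracting features
    recovers the generating counts exactly.
    """
    vocab = vocabulary or toy_vocabulary()
    for cat in CATEGORIES:
        if any(
            params.get(cat) and params[cat].mean > 0 and not vocab.pool(cat)
            for params in config.rates.values()
        ):
            raise ValidationError(f"category {cat!r} requested but vocabulary empty")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    transcripts: list[Transcript] = []
    tables: dict[tuple[str, str], list[list[Token]]] = {}
    metadata: list[ParticipantMeta] = []
    truth_rows = []
    for pid, group, task, counts, duration in _draw_rows(config, rng):
        tokens: list[Token] = []
        for cat in CATEGORIES:
            pool = vocab.pool(cat)
            for _ in range(counts[cat]):
                lemma = pool[int(rng.integers(len(pool)))]
                tokens.append(Token(lemma, lemma, _CATEGORY_TAGS[cat]))
        if not tokens:  # degenerate sample: keep one filler so MLU is defined
            lemma = vocab.filler[0]
            tokens = [Token(lemma, lemma, _CATEGORY_TAGS["filler"])]
            counts = dict(counts, filler=1)
        order = rng.permutation(len(tokens))
        tokens = [tokens[i] for i in order]
        utterances: list[list[Token]] = []
        i = 0
        while i < len(tokens):
            length = max(1, int(rng.poisson(config.utterance_mean_len)))
            utt = tokens[i : i + length]
            utt.append(Token(".", ".", "interp"))
            utterances.append(utt)
            i += length
        transcripts.append(
            Transcript(
                participant_id=pid,
                group=Group(group),
                task=Task(task),
                duration_s=round(duration, 1),
                utterances=[
                    Utterance("PAR", [t.surface for t in utt]) for utt in utterances
                ],
            )
        )
        tables[(pid, task)] = utterances
        metadata.append(
            ParticipantMeta(pid, Group(group), Task(task), round(duration, 1))
        )
        truth_rows.append(
            {
                "participant_id": pid,
                "group": group,
                "task": task,
                "n_pos": counts["pos"],
                "n_neg": counts["neg"],
                "n_dav": counts["dav"],
                "n_iav": counts["iav"],
                "n_sv": counts["sv"],
                "n_filler": counts["filler"],
                "abstraction": counts["dav"] + 2 * counts["iav"] + 3 * counts["sv"],
            }
        )
    return SyntheticCorpus(
        corpus=Corpus(transcripts),
        token_tables=tables,
        metadata=metadata,
        truth=pd.DataFrame(truth_rows),
    )


def write_corpus(synth: SyntheticCorpus, out_dir: PathLike) -> None:
    """Emit CHAT files, token tables and the metadata CSV."""
    out = Path(out_dir)
    (out / "chat").mkdir(parents=True, exist_ok=True)
    (out / "tokens").mkdir(parents=True, exist_ok=True)
    for transcript in synth.corpus:
        stem = f"{transcript.participant_id}_{transcript.task.value}"
        lines = [
            "@UTF8",
            "@Begin",
            "@Languages:\tpol",
            f"@ID:\tpol|narsent|PAR|{transcript.participant_id}|"
            f"|{transcript.group.value if transcript.group else ''}||Participant||",
        ]
        for utt in transcript.utterances:
            lines.append("*PAR:\t" + " ".join(utt.tokens))
        lines.append("@End")
        (out / "chat" / f"{stem}.cha").write_text(
            "\n".join(lines) + "\n", encoding="utf-8"
        )
        write_token_table(
            synth.token_tables[(transcript.participant_id, transcript.task.value)],
            out / "tokens" / f"{stem}.tsv",
        )
    write_metadata(synth.metadata, out / "metadata.csv")


def power_curve(
    effect_sizes: Sequence[float],
    n_values: Sequence[int],
    reps: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo power of the gated two-group test for normal shifts.

    Returns one row per (effect, n) with the empirical rejection rate
    and its Monte-Carlo standard error.
    """
    from .stats import compare_groups  # local import avoids cycle at module load

    if reps < 100:
        raise ValidationError("reps must be >= 100")
    rng = np.random.default_rng(seed)
    rows = []
    for d in effect_sizes:
        for n in n_values:
            hits = 0
            for _ in range(reps):
                a = rng.normal(0.0, 1.0, n)
                b = rng.normal(d, 1.0, n)
                if compare_groups(a, b, alpha=alpha).p < alpha:
                    hits += 1
            power = hits / reps
            rows.append(
                {
                    "effect": d,
                    "n": n,
                    "power": power,
                    "mc_se": math.sqrt(power * (1 - power) / reps),
                    "reps": reps,
                }
            )
    return pd.DataFrame(rows)
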