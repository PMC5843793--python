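"""Synthetic caDSR-like corpora with known temporal structure.

Real CDE exports cannot be redistributed, so every downstream module is
exercised against generated corpora that emulate the caDSR naming style:
LongName/PreferredDefinition text templates with temporal keywords
planted at a controlled prevalence, gold extraction labels, and planted
annotator behaviour with exact disagreement allocation.

Noise and disagreement fractions are allocated exactly (``floor(rate *
n)``, remainder left clean) rather than sampled, so evaluation-recovery
tests are exact identities, not statistical approximations.  Everything
is deterministic given the seed: two runs with the same spec produce
byte-identical XML and annotation files.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .cadsr import (
    AnnotationCategory,
    AnnotationRecord,
    CDERecord,
    write_annotations,
    write_cadsr_xml,
)
from .errors import TeoCdeError

__all__ = ["CorpusSpec", "GoldLabel", "generate_corpus", "plant_annotators",
           "write_corpus_files"]

#: Default pattern mix: the observed relative frequencies of the ten
#: built-in templates (rank percentages renormalized to sum to 1).
DEFAULT_PATTERN_MIX: dict[str, float] = {
    "P1": 31.0, "P2": 19.5, "P3": 15.0, "P4": 7.0, "P5": 5.9,
    "P6": 5.4, "P7": 4.4, "P8": 4.2, "P9": 2.8, "P10": 1.8,
}
_TOTAL = sum(DEFAULT_PATTERN_MIX.values())
DEFAULT_PATTERN_MIX = {k: v / _TOTAL for k, v in DEFAULT_PATTERN_MIX.items()}

#: One realizable surface form per keyword group (five groups, matching
#: the built-in lexicon), chosen per record by the keyword mix.
_GROUP_SURFACES: tuple[tuple[str, ...], ...] = (
    ("January", "February", "April", "August", "October", "Today",
     "Morning", "Night", "Date"),
    ("Seconds", "Minutes", "Hours", "Days", "Weeks", "Months", "Years"),
    ("Before", "Prior To", "Ago", "Previously", "Post", "Subsequent",
     "Concurrent", "During", "After", "Within", "Until", "When"),
    ("Recurrent", "Frequent", "Intermittent", "Periodic", "Repeated"),
    ("Interval",),
)

# Vocabulary guaranteed free of lexicon keywords (checked in tests).
_TOPICS = (
    "Hemoglobin", "Specimen", "Tumor", "Lesion", "Biopsy", "Chemotherapy",
    "Radiation", "Questionnaire", "Laboratory", "Margin", "Lymph Node",
    "Platelet", "Creatinine", "Glucose", "Bilirubin", "Albumin",
    "Neutrophil", "Karnofsky", "Histology", "Metastasis",
)
_SUFFIXES = (
    "Assessment", "Indicator", "Score", "Type", "Status", "Grade", "Scale",
    "Result", "Value", "Code", "Name", "Identifier", "Text", "Term",
    "Quantity", "Count",
)
#: Near-miss tokens that contain a keyword substring but must be
#: rejected by word-boundary matching.
_NEAR_MISSES = ("Candidate", "Update", "Mandate", "Postal", "Validated",
                "Whenever", "Interviewer")


@dataclass
class CorpusSpec:
    """Generation parameters for a synthetic CDE corpus.

    ``prevalence`` is the fraction of records carrying a temporal
    keyword; ``fp_noise`` plants near-miss tokens in that fraction of
    negatives; ``fn_noise`` obfuscates the keyword in that fraction of
    positives (gold stays positive, so the parser must miss them).
    """

    n_records: int
    prevalence: float = 0.4
    keyword_mix: Sequence[float] = (0.35, 0.15, 0.35, 0.05, 0.10)
    pattern_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PATTERN_MIX)
    )
    fp_noise: float = 0.0
    fn_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 0:
            raise TeoCdeError("n_records must be non-negative")
        for name in ("prevalence", "fp_noise", "fn_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise TeoCdeError(f"{name} must lie in [0, 1]")
        if abs(sum(self.keyword_mix) - 1.0) > 1e-9 or len(self.keyword_mix) != 5:
            raise TeoCdeError("keyword_mix must be five weights summing to 1")
        if self.pattern_mix and abs(sum(self.pattern_mix.values()) - 1.0) > 1e-9:
            raise TeoCdeError("pattern_mix weights must sum to 1")


@dataclass(frozen=True)
class GoldLabel:
    """Ground truth for one generated record."""

    public_id: str
    is_time_relevant: bool
    planted_keywords: tuple[str, ...] = ()
    planted_pattern_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.is_time_relevant != (self.planted_pattern_id is not None):
            raise TeoCdeError(
                "planted_pattern_id must be present exactly for "
                "time-relevant records"
            )


def _obfuscate(keyword: str) -> str:
    """Break a keyword's surface so no lexicon entry can match it (a
    vowel is swapped mid-word)."""
    mid = len(keyword) // 2
    return keyword[:mid] + "q" + keyword[mid + 1:]


def generate_corpus(spec: CorpusSpec) -> tuple[list[CDERecord], list[GoldLabel]]:
    """Generate records and gold labels; deterministic given the seed.

    Exactly ``floor(prevalence * n_records)`` records are time-relevant.
    Positives embed a keyword surface in LongName (and usually
    PreferredDefinition); negatives draw only from keyword-free
    vocabulary, except the ``fp_noise`` fraction which receives a
    near-miss token that word-boundary matching must reject.
    """
    rng = random.Random(spec.seed)
    n_pos = math.floor(spec.prevalence * spec.n_records)
    if n_pos < 1 and spec.pattern_mix and spec.prevalence > 0:
        import warnings

        warnings.warn("prevalence * n_records < 1: generating zero positives")
    positions = set(rng.sample(range(spec.n_records), n_pos))
    n_fn = math.floor(spec.fn_noise * n_pos)
    n_fp = math.floor(spec.fp_noise * (spec.n_records - n_pos))
    pattern_ids = list(spec.pattern_mix) or [None]
    weights = [spec.pattern_mix[p] for p in pattern_ids] if spec.pattern_mix else [1.0]

    records, gold = [], []
    pos_seen = neg_seen = 0
    for i in range(spec.n_records):
        public_id = str(9000000 + i)
        topic = rng.choice(_TOPICS)
        suffix = rng.choice(_SUFFIXES)
        if i in positions:
            group = rng.choices(range(5), weights=list(spec.keyword_mix))[0]
            keyword = rng.choice(_GROUP_SURFACES[group])
            pattern_id = (
                rng.choices(pattern_ids, weights=weights)[0] if spec.pattern_mix else None
            )
            obfuscated = pos_seen < n_fn
            pos_seen += 1
            surface = _obfuscate(keyword) if obfuscated else keyword
            long_name = f"{topic} {surface} {suffix}"
            definition = (
                f"Text term to describe the {topic.lower()} "
                f"{surface.lower()} {suffix.lower()}."
            )
            records.append(
                CDERecord(
                    num=i + 1,
                    public_id=public_id,
                    long_name=long_name,
                    preferred_name=f"{public_id}v1.0",
                    preferred_definition=definition,
                )
            )
            gold.append(
                GoldLabel(
                    public_id=public_id,
                    is_time_relevant=True,
                    planted_keywords=(keyword,),
                    planted_pattern_id=pattern_id or "P1",
                )
            )
        else:
            extra = ""
            if neg_seen < n_fp:
                extra = f" {rng.choice(_NEAR_MISSES)}"
            neg_seen += 1
            long_name = f"{topic} {suffix}{extra}"
            definition = f"Text term to describe the {topic.lower()} {suffix.lower()}."
            records.append(
                CDERecord(
                    num=i + 1,
                    public_id=public_id,
                    long_name=long_name,
                    preferred_name=f"{public_id}v1.0",
                    preferred_definition=definition,
                )
            )
            gold.append(GoldLabel(public_id=public_id, is_time_relevant=False))
    return records, gold


def plant_annotators(
    gold: Sequence[GoldLabel],
    n_annotators: int = 3,
    disagreement_rates: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    new_pattern_fraction: float = 0.0,
    cannot_represent_fraction: float = 0.0,
) -> dict[str, list[AnnotationRecord]]:
    """Plant per-annotator assignments over the gold labels.

    Over the time-relevant records, ``floor(rate * n)`` CDEs are forced
    into the one-difference and all-different agreement categories (one
    annotator, or all three, deviating to other pattern ids); optional
    fractions are reassigned to the *new pattern* and *cannot represent*
    categories (consistently across annotators).  Non-time-relevant gold
    records are annotated *not time-related*.  Returns annotator id ->
    ordered annotation records.
    """
    one_rate, all_rate = disagreement_rates
    if one_rate < 0 or all_rate < 0 or one_rate + all_rate > 1:
        raise TeoCdeError("disagreement rates must be non-negative and sum to <= 1")
    rng = random.Random(seed)
    relevant = [g for g in gold if g.is_time_relevant]
    n_rel = len(relevant)
    k_cannot = math.floor(cannot_represent_fraction * n_rel)
    k_new = math.floor(new_pattern_fraction * n_rel)
    k_one = math.floor(one_rate * n_rel)
    k_all = math.floor(all_rate * n_rel)
    if k_cannot + k_new > n_rel:
        raise TeoCdeError("category fractions exceed the relevant stratum")

    annotator_ids = [f"A{i + 1}" for i in range(n_annotators)]
    out: dict[str, list[AnnotationRecord]] = {a: [] for a in annotator_ids}

    # deterministic strata: [cannot][new][existing]; disagreement is then
    # allocated over the pattern-bearing records from the end so the two
    # allocations cannot collide with the cannot-represent stratum
    pattern_pool = sorted({g.planted_pattern_id for g in relevant} | {"P1", "P2", "P3"})

    def other_patterns(p: str, k: int) -> list[str]:
        alts = [q for q in pattern_pool if q != p]
        return [alts[j % len(alts)] for j in range(k)]

    bearing = relevant[k_cannot:]
    if k_one + k_all > len(bearing):
        raise TeoCdeError("disagreement rates exceed the pattern-bearing stratum")
    all_diff_ids = {g.public_id for g in bearing[len(bearing) - k_all:]}
    one_diff_ids = {
        g.public_id
        for g in bearing[len(bearing) - k_all - k_one : len(bearing) - k_all]
    }

    for idx, g in enumerate(relevant):
        if idx < k_cannot:
            for a in annotator_ids:
                out[a].append(
                    AnnotationRecord(g.public_id, a, AnnotationCategory.CANNOT_REPRESENT)
                )
            continue
        category = (
            AnnotationCategory.NEW_PATTERN
            if idx < k_cannot + k_new
            else AnnotationCategory.EXISTING_PATTERN
        )
        base = g.planted_pattern_id if category is AnnotationCategory.EXISTING_PATTERN \
            else f"N{idx - k_cannot + 1}"
        if g.public_id in all_diff_ids:
            variants = [base] + other_patterns(base, n_annotators - 1)
            for a, p in zip(annotator_ids, variants):
                out[a].append(AnnotationRecord(g.public_id, a, category, p))
        elif g.public_id in one_diff_ids:
            deviant = rng.randrange(n_annotators)
            alt = other_patterns(base, 1)[0]
            for j, a in enumerate(annotator_ids):
                out[a].append(
                    AnnotationRecord(g.public_id, a, category, alt if j == deviant else base)
                )
        else:
            for a in annotator_ids:
                out[a].append(AnnotationRecord(g.public_id, a, category, base))

    for g in gold:
        if not g.is_time_relevant:
            for a in annotator_ids:
                out[a].append(
                    AnnotationRecord(g.public_id, a, AnnotationCategory.NOT_TIME_RELATED)
                )
    return out


def write_corpus_files(
    spec: CorpusSpec,
    out_dir,
    disagreement_rates: tuple[float, float] = (0.0, 0.0),
) -> dict[str, str]:
    """Generate a corpus and write corpus.xml, gold.tsv and one
    annotations_A*.tsv per annotator; returns path names written."""
    import os

    records, gold = generate_corpus(spec)
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    xml_path = os.path.join(out_dir, "corpus.xml")
    with open(xml_path, "wb") as fh:
        fh.write(write_cadsr_xml(records))
    paths["corpus"] = xml_path
    gold_path = os.path.join(out_dir, "gold.tsv")
    with open(gold_path, "w", encoding="utf-8") as fh:
        fh.write("public_id\tis_time_relevant\tplanted_keywords\tplanted_pattern_id\n")
        for g in gold:
            fh.write(
                f"{g.public_id}\t{int(g.is_time_relevant)}\t"
                f"{','.join(g.planted_keywords) or '-'}\t"
                f"{g.planted_pattern_id or '-'}\n"
            )
    paths["gold"] = gold_path
    annotations = plant_annotators(
        gold, seed=spec.seed, disagreement_rates=disagreement_rates
    )
    for annotator_id, recs in annotations.items():
        path = os.path.join(out_dir, f"annotations_{annotator_id}.tsv")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(write_annotations(recs))
        paths[annotator_id] = path
    return paths
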