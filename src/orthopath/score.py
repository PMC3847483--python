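"""Annotation confidence scores and MS–CS region classification.

Each evidence item carries a weight H*F, where H is the match-quality
weight (1 for a reciprocal best hit, 0.5 for a second-pass-confirmed hit)
and F the function-clarity weight (1 clear, 0.5 otherwise).  Over the
N_m template species that identified a function,

    MS = sum(H_i * F_i) / N_m      (match score: alignment quality)
    CS = sum(H_i * F_i) / N_t      (conservation score: spread across
                                    the N_t templates employed)

Both scores live in (0, 1]; CS = MS * N_m / N_t.  The MS–CS plane is
partitioned into confidence regions: A (low, MS below the MS threshold),
B (high: strong match, weak conservation), C (extremely high: both
strong).  The region boundaries are qualitative in origin and therefore
configurable; defaults are MS >= 0.7 and CS >= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .annotate import AnnotationCandidate, EvidenceItem

SCORE_TABLE_COLUMNS = ("query_id", "function", "n_m", "MS", "CS", "region", "validated")


@dataclass(frozen=True)
class ScoreConfig:
    n_templates: int = 5
    region_ms_threshold: float = 0.7
    region_cs_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.n_templates < 1:
            raise ValueError("n_templates must be a positive integer")
        for t in (self.region_ms_threshold, self.region_cs_threshold):
            if not (0 < t <= 1):
                raise ValueError("region thresholds must lie in (0, 1]")


def compute_ms(evidence: Sequence[EvidenceItem]) -> float:
    """Match score: mean H*F over the species that identified the function."""
    if not evidence:
        raise ValueError("a protein with no evidence is unannotated, not score 0")
    return sum(e.weight for e in evidence) / len(evidence)


def compute_cs(evidence: Sequence[EvidenceItem], config: ScoreConfig | None = None) -> float:
    """Conservation score: summed H*F over the total number of templates N_t."""
    config = config or ScoreConfig()
    if not evidence:
        raise ValueError("a protein with no evidence is unannotated, not score 0")
    if len(evidence) > config.n_templates:
        raise ValueError(
            f"evidence from {len(evidence)} species exceeds N_t={config.n_templates}"
        )
    return sum(e.weight for e in evidence) / config.n_templates


def classify_region(ms: float, cs: float, config: ScoreConfig | None = None) -> str:
    """Assign an (MS, CS) pair to confidence region A, B or C."""
    config = config or ScoreConfig()
    if not (0 < cs <= ms <= 1):
        raise ValueError(f"scores must satisfy 0 < CS <= MS <= 1, got MS={ms}, CS={cs}")
    if ms < config.region_ms_threshold:
        return "A"
    if cs < config.region_cs_threshold:
        return "B"
    return "C"


@dataclass
class AnnotatedProtein:
    """A scored (query protein, function) annotation."""

    candidate: AnnotationCandidate
    ms: float
    cs: float
    region: str
    validated: bool = False

    @property
    def query_id(self) -> str:
        return self.candidate.query_id

    @property
    def gene_id(self) -> str:
        # 12-digit gene/transcript convention where applicable
        import re

        m = re.match(r"^(\d{6})_(?:\d{6}|x{6})$", self.candidate.query_id)
        return m.group(1) if m else self.candidate.query_id

    @property
    def function_label(self) -> str:
        return self.candidate.function_label

    @property
    def ec_numbers(self) -> tuple[str, ...]:
        return self.candidate.ec_numbers

    @property
    def n_m(self) -> int:
        return self.candidate.n_m

    def to_dict(self) -> dict:
        return {
            "candidate": self.candidate.to_dict(),
            "ms": self.ms,
            "cs": self.cs,
            "region": self.region,
            "validated": self.validated,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnnotatedProtein":
        return cls(
            candidate=AnnotationCandidate.from_dict(d["candidate"]),
            ms=d["ms"], cs=d["cs"], region=d["region"],
            validated=d.get("validated", False),
        )


def score_table(
    candidates: Iterable[AnnotationCandidate],
    config: ScoreConfig | None = None,
) -> tuple[list[AnnotatedProtein], pd.DataFrame]:
    """Score every candidate and build the MS–CS scatter table."""
    config = config or ScoreConfig()
    annotated: list[AnnotatedProtein] = []
    for cand in candidates:
        ms = compute_ms(cand.evidence)
        cs = compute_cs(cand.evidence, config)
        annotated.append(
            AnnotatedProtein(candidate=cand, ms=ms, cs=cs, region=classify_region(ms, cs, config))
        )
    rows = [
        (a.query_id, a.function_label, a.n_m, a.ms, a.cs, a.region, a.validated)
        for a in annotated
    ]
    df = pd.DataFrame(rows, columns=list(SCORE_TABLE_COLUMNS))
    return annotated, df


def annotations_to_frame(annotated: Iterable[AnnotatedProtein]) -> pd.DataFrame:
    rows = [
        (a.query_id, a.function_label, a.n_m, a.ms, a.cs, a.region, a.validated)
        for a in annotated
    ]
    return pd.DataFrame(rows, columns=list(SCORE_TABLE_COLUMNS))


def write_score_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def plot_ms_cs(df: pd.DataFrame, path, config: ScoreConfig | None = None) -> None:
    """MS–CS scatter with the region boundaries drawn as lines."""
    config = config or ScoreConfig()
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    sub = df[~df["validated"]]
    ax.scatter(sub["MS"], sub["CS"], marker="x", color="k", label="annotated")
    val = df[df["validated"]]
    if len(val):
        ax.scatter(
            val["MS"], val["CS"], facecolors="none", edgecolors="r", s=80,
            label="validated",
        )
    ax.axvline(config.region_ms_threshold, ls="--", lw=0.8, color="grey")
    ax.axhline(config.region_cs_threshold, ls="--", lw=0.8, color="grey")
    ax.set_xlabel("match score (MS)")
    ax.set_ylabel("conservation score (CS)")
    ax.set_xlim(0, 1.05)
    ax.set_ylim(0, 1.05)
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
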