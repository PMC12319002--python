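"""Delphi-round statistics: descriptives, panel authority, concordance,
and rule-based indicator screening.

Conventions (all configurable where noted):

* standard deviation is the population SD (divisor ``N``) — the convention
  under which integer 1–5 score multisets reproduce the reference
  mean ± SD pairs at two decimals;
* Kendall's W uses mid-rank ties with the tie-corrected denominator,
  ``W = 12·S / (m²(n³−n) − m·ΣT)``, and is tested via ``χ² = m(n−1)·W``
  against the upper chi-square tail with ``n−1`` degrees of freedom;
* the expert authority coefficient is ``Cr = (Ca + Cs)/2`` where ``Ca`` sums
  four graded judgment-basis components and ``Cs`` maps self-rated
  familiarity onto {0.2, 0.4, 0.6, 0.8, 1.0}.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ScorePanel",
    "IndicatorStats",
    "AuthorityReport",
    "ExpertAuthority",
    "ConcordanceReport",
    "ScreeningConfig",
    "ScreeningDecision",
    "RoundReport",
    "indicator_stats",
    "response_rate",
    "authority_coefficient",
    "kendalls_w",
    "screen_indicators",
    "run_round",
    "find_score_multiset",
    "load_reference_stats",
    "load_reference_score_sets",
    "read_score_panel",
]

# judgment-basis value tables: grade -> contribution to Ca
CA_TABLES: dict[str, dict[str, float]] = {
    "theory": {"large": 0.3, "medium": 0.2, "small": 0.1},
    "practice": {"large": 0.5, "medium": 0.4, "small": 0.3},
    "reference": {"large": 0.1, "medium": 0.1, "small": 0.1},
    "intuition": {"large": 0.1, "medium": 0.1, "small": 0.1},
}

FAMILIARITY_LEVELS: dict[str, float] = {
    "very unfamiliar": 0.2,
    "unfamiliar": 0.4,
    "moderate": 0.6,
    "familiar": 0.8,
    "very familiar": 1.0,
}

CREDIBLE_CR = 0.7


class PanelError(ValueError):
    """Raised for malformed or inconsistent score-panel inputs."""


@dataclass
class ScorePanel:
    """One Delphi round: experts × indicators integer scores in 1..5.

    ``necessity_votes[e, i]`` is True where expert ``e`` flagged indicator
    ``i`` as not necessary. ``judgment_grades`` maps the four judgment-basis
    dimensions to a grade per expert; ``familiarity`` is one of the five
    familiarity labels (or its numeric value) per expert.
    """

    round_id: int
    expert_ids: list[str]
    indicator_ids: list[str]
    scores: np.ndarray
    necessity_votes: np.ndarray | None = None
    judgment_grades: list[dict[str, str]] | None = None
    familiarity: list[str | float] | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        m, n = len(self.expert_ids), len(self.indicator_ids)
        if self.scores.shape != (m, n):
            raise PanelError(
                f"score matrix shape {self.scores.shape} does not match "
                f"{m} experts x {n} indicators"
            )
        if m == 0 or n == 0:
            raise PanelError("empty panel")
        if not np.issubdtype(self.scores.dtype, np.integer):
            if not np.all(self.scores == np.round(self.scores)):
                raise PanelError("scores must be integers")
            self.scores = self.scores.astype(int)
        if self.scores.min() < 1 or self.scores.max() > 5:
            bad = self.scores[(self.scores < 1) | (self.scores > 5)][0]
            raise PanelError(f"score {bad} outside 1..5")
        if self.necessity_votes is not None:
            self.necessity_votes = np.asarray(self.necessity_votes, dtype=bool)
            if self.necessity_votes.shape != (m, n):
                raise PanelError("necessity vote matrix shape mismatch")

    @property
    def n_experts(self) -> int:
        return len(self.expert_ids)

    @property
    def n_indicators(self) -> int:
        return len(self.indicator_ids)


@dataclass(frozen=True)
class IndicatorStats:
    """Full-precision descriptives for one indicator; round only in reports."""

    indicator_id: str
    mean: float
    sd: float
    cv: float
    pct_not_necessary: float = 0.0

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        return (
            round_half_up(self.mean, ndigits),
            round_half_up(self.sd, ndigits),
            round_half_up(self.cv, ndigits),
        )


@dataclass(frozen=True)
class ExpertAuthority:
    expert_id: str
    ca: float
    cs: float

    @property
    def cr(self) -> float:
        return (self.ca + self.cs) / 2.0


@dataclass(frozen=True)
class AuthorityReport:
    experts: tuple[ExpertAuthority, ...]

    @property
    def panel_cr(self) -> float:
        return float(np.mean([e.cr for e in self.experts]))

    @property
    def credible(self) -> bool:
        return self.panel_cr >= CREDIBLE_CR


@dataclass(frozen=True)
class ConcordanceReport:
    w: float
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class ScreeningConfig:
    """Thresholds for the retain / review / delete rules."""

    retain_mean: float = 4.0
    retain_cv: float = 0.25
    delete_mean: float = 3.5
    delete_cv: float = 0.30
    max_not_necessary: float = 0.30


@dataclass(frozen=True)
class ScreeningDecision:
    indicator_id: str
    verdict: str  # retain | review | delete
    triggered_rules: tuple[str, ...]


@dataclass(frozen=True)
class RoundReport:
    round_id: int
    stats: tuple[IndicatorStats, ...]
    authority: AuthorityReport | None
    concordance: ConcordanceReport
    decisions: tuple[ScreeningDecision, ...]
    converged: bool


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal-style rounding (0.005 -> 0.01), as report tables expect."""
    q = 10.0**ndigits
    return float(np.floor(abs(x) * q + 0.5) / q * np.sign(x)) if x else 0.0


# -- descriptives ----------------------------------------------------------


def indicator_stats(panel: ScorePanel) -> list[IndicatorStats]:
    """Per-indicator mean, population SD, CV and not-necessary vote share."""
    out = []
    votes = panel.necessity_votes
    for j, iid in enumerate(panel.indicator_ids):
        col = panel.scores[:, j].astype(float)
        mean = float(col.mean())
        sd = float(col.std())  # population convention, divisor N
        cv = sd / mean if mean > 0 else 0.0
        pct = float(votes[:, j].mean()) if votes is not None else 0.0
        out.append(IndicatorStats(iid, mean, sd, cv, pct))
    return out


def response_rate(sent: int, returned_valid: int) -> float:
    """Effective recovery rate: valid returns over questionnaires sent."""
    if sent <= 0:
        raise PanelError("no questionnaires sent")
    if not 0 <= returned_valid <= sent:
        raise PanelError("returned_valid outside [0, sent]")
    return returned_valid / sent


# -- expert authority ------------------------------------------------------


def authority_coefficient(
    panel: ScorePanel,
    ca_tables: Mapping[str, Mapping[str, float]] | None = None,
    familiarity_levels: Mapping[str, float] | None = None,
) -> AuthorityReport:
    """Per-expert Ca, Cs and Cr = (Ca+Cs)/2, plus the panel-mean Cr."""
    ca_tables = ca_tables or CA_TABLES
    fam_map = familiarity_levels or FAMILIARITY_LEVELS
    if panel.judgment_grades is None or panel.familiarity is None:
        raise PanelError("authority inputs (grades, familiarity) missing")
    experts = []
    for eid, grades, fam in zip(
        panel.expert_ids, panel.judgment_grades, panel.familiarity
    ):
        ca = 0.0
        for dim, table in ca_tables.items():
            if dim not in grades:
                raise PanelError(f"expert {eid}: missing grade for {dim!r}")
            grade = grades[dim]
            if grade not in table:
                raise PanelError(f"expert {eid}: unknown grade {grade!r} for {dim!r}")
            ca += table[grade]
        if isinstance(fam, str):
            if fam not in fam_map:
                raise PanelError(f"expert {eid}: unknown familiarity {fam!r}")
            cs = fam_map[fam]
        else:
            cs = float(fam)
            if cs not in set(fam_map.values()):
                raise PanelError(f"expert {eid}: familiarity value {cs} not a level")
        experts.append(ExpertAuthority(eid, ca, cs))
    return AuthorityReport(tuple(experts))


# -- concordance -----------------------------------------------------------


def kendalls_w(panel: ScorePanel | np.ndarray) -> ConcordanceReport:
    """Tie-corrected Kendall coefficient of concordance over a score panel.

    Scores are converted to within-expert mid-ranks. With rank sums ``R_j``,
    ``S = Σ (R_j − R̄)²`` and per-expert tie term ``T = Σ(t³ − t)``,

        W = 12·S / (m²(n³ − n) − m·ΣT)

    The significance test uses ``χ² = m(n−1)W`` on ``n−1`` df. A degenerate
    panel where every expert ties all items returns W = 0.
    """
    scores = panel.scores if isinstance(panel, ScorePanel) else np.asarray(panel)
    m, n = scores.shape
    if m < 2 or n < 2:
        raise PanelError("concordance needs at least 2 experts and 2 indicators")
    ranks = np.vstack([sps.rankdata(row) for row in scores])
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    tie_term = 0.0
    for row in scores:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float((counts**3 - counts).sum())
    denom = m * m * (n**3 - n) - m * tie_term
    w = 12.0 * s / denom if denom > 0 else 0.0
    chi2 = m * (n - 1) * w
    df = n - 1
    p = float(sps.chi2.sf(chi2, df))
    return ConcordanceReport(w=w, chi2=chi2, df=df, p=p)


# -- screening -------------------------------------------------------------


def screen_indicators(
    stats: Sequence[IndicatorStats], config: ScreeningConfig | None = None
) -> list[ScreeningDecision]:
    """Apply the retain / review / delete rules to per-indicator stats.

    Delete if the not-necessary vote share exceeds ``max_not_necessary``, the
    mean falls below ``delete_mean``, or the CV exceeds ``delete_cv``. Retain
    if mean ≥ ``retain_mean`` and CV < ``retain_cv``. Anything else is flagged
    ``review`` for expert re-argumentation. Pure function of its inputs.
    """
    config = config or ScreeningConfig()
    decisions = []
    for st in stats:
        delete_rules = []
        if st.pct_not_necessary > config.max_not_necessary:
            delete_rules.append("not_necessary_share_gt_max")
        if st.mean < config.delete_mean:
            delete_rules.append("mean_lt_delete_threshold")
        if st.cv > config.delete_cv:
            delete_rules.append("cv_gt_delete_threshold")
        if delete_rules:
            decisions.append(
                ScreeningDecision(st.indicator_id, "delete", tuple(delete_rules))
            )
        elif st.mean >= config.retain_mean and st.cv < config.retain_cv:
            decisions.append(
                ScreeningDecision(
                    st.indicator_id,
                    "retain",
                    ("mean_ge_retain_threshold", "cv_lt_retain_threshold"),
                )
            )
        else:
            rules = []
            if st.mean < config.retain_mean:
                rules.append("mean_below_retain_threshold")
            if st.cv >= config.retain_cv:
                rules.append("cv_at_or_above_retain_threshold")
            decisions.append(
                ScreeningDecision(st.indicator_id, "review", tuple(rules))
            )
    return decisions


# -- round orchestration ---------------------------------------------------


def run_round(hierarchy, panel: ScorePanel, config: ScreeningConfig | None = None):
    """Aggregate one round's stats, authority, concordance and decisions.

    Every scored id must be an active indicator of ``hierarchy`` (any level:
    panels may score non-leaf rows directly; parents are never imputed from
    children). The convergence flag is ``W ≥ 0.5 and all CV < 0.25``, exposed
    for the stop-correspondence decision.
    """
    active_ids = {i.id for i in hierarchy.active()}
    unknown = [iid for iid in panel.indicator_ids if iid not in active_ids]
    if unknown:
        raise PanelError(
            f"panel scores inactive or unknown indicator(s): {', '.join(unknown)}"
        )
    stats = indicator_stats(panel)
    authority = None
    if panel.judgment_grades is not None and panel.familiarity is not None:
        authority = authority_coefficient(panel)
    concordance = kendalls_w(panel)
    cfg = config or ScreeningConfig()
    decisions = screen_indicators(stats, cfg)
    converged = concordance.w >= 0.5 and all(
        st.cv < cfg.retain_cv for st in stats
    )
    return RoundReport(
        round_id=panel.round_id,
        stats=tuple(stats),
        authority=authority,
        concordance=concordance,
        decisions=tuple(decisions),
        converged=converged,
    )


# -- reference data and utilities -----------------------------------------


def find_score_multiset(
    mean: float, sd: float, n: int = 15, ndigits: int = 2
) -> list[int]:
    """Smallest-lexicographic (descending) multiset of ``n`` integer scores in
    1..5 whose rounded mean and population SD equal the targets.

    Raises ``ValueError`` when no such multiset exists.
    """
    for combo in itertools.combinations_with_replacement(range(5, 0, -1), n):
        arr = np.array(combo, dtype=float)
        if (
            round(arr.mean(), ndigits) == round(mean, ndigits)
            and round(arr.std(), ndigits) == round(sd, ndigits)
        ):
            return sorted(combo, reverse=True)
    raise ValueError(f"no {n}-score multiset reproduces mean={mean}, sd={sd}")


def _data_file(name: str) -> Path:
    with resources.as_file(
        resources.files("delphiahp.data").joinpath(name)
    ) as p:
        return Path(p)


def load_reference_stats() -> pd.DataFrame:
    """Bundled reference table: per-indicator mean, SD, CV and final weight."""
    return pd.read_csv(_data_file("reference_means.csv"), dtype={"indicator_id": str})


def load_reference_score_sets() -> dict[str, list[int]]:
    """Bundled 15-score multisets reproducing each reference (mean, SD) pair."""
    return json.loads(_data_file("reference_score_sets.json").read_text())


def read_score_panel(
    scores_path: str | Path,
    round_id: int = 1,
    votes_path: str | Path | None = None,
    authority_path: str | Path | None = None,
) -> ScorePanel:
    """Assemble a ScorePanel from CSV files.

    ``scores_path``: first column ``expert_id``, remaining columns indicator
    ids, integer cells. ``votes_path``: same layout with 0/1 cells.
    ``authority_path``: columns ``expert_id, theory, practice, reference,
    intuition, familiarity``.
    """
    df = pd.read_csv(scores_path, dtype={"expert_id": str})
    if "expert_id" not in df.columns:
        raise PanelError("score CSV must have an expert_id column")
    expert_ids = df["expert_id"].tolist()
    indicator_ids = [c for c in df.columns if c != "expert_id"]
    scores = df[indicator_ids].to_numpy()
    votes = None
    if votes_path is not None:
        vdf = pd.read_csv(votes_path, dtype={"expert_id": str})
        if vdf["expert_id"].tolist() != expert_ids:
            raise PanelError("vote CSV expert ids do not match score CSV")
        votes = vdf[indicator_ids].to_numpy().astype(bool)
    grades = fam = None
    if authority_path is not None:
        adf = pd.read_csv(authority_path, dtype={"expert_id": str}).set_index(
            "expert_id"
        )
        try:
            adf = adf.loc[expert_ids]
        except KeyError as e:
            raise PanelError(f"authority CSV missing expert {e}") from None
        grades = [
            {k: row[k] for k in ("theory", "practice", "reference", "intuition")}
            for _, row in adf.iterrows()
        ]
        fam = list(adf["familiarity"])
    return ScorePanel(
        round_id=round_id,
        expert_ids=expert_ids,
        indicator_ids=indicator_ids,
        scores=scores,
        necessity_votes=votes,
        judgment_grades=grades,
        familiarity=fam,
    )
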