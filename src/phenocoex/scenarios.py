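"""Per-cell-line transitions, differential-scenario calls, phenotype filter.

Within each cell line a gene pair has a control label and a treated label
(S / NS / NA / EXCLUDED from :mod:`phenocoex.coexpression`). Their combination
maps to a transition code; transitions across cell lines combine into one of
three differential scenarios:

* **DS1** — gain of correlation: every Phenotype-A line goes {NS, NA} -> S.
* **DS2** — loss of correlation: every Phenotype-A line goes S -> {NS, NA}.
* **DS3** — retained significance with a significant change in correlation
  strength (S -> S with a positive strength-change test) in every A line.

Identical per-line patterns are not required within a scenario (one A line may
gain from NS while the other gains from NA). The phenotype filter then demands
that every Phenotype-B line shows a *non-differential* pattern — NS under both
treatments, NA under both, or S under both with no strength change — so that
the rewiring is attributable to the responsive phenotype rather than to the
treatment per se.

The strength-change test for S -> S pairs is a two-sided Fisher r-to-z
comparison. At n = 5 it has minimal power, which is the expected reason DS3
calls are rare in small-n designs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_up
from .coexpression import (
    LABEL_EXCLUDED,
    LABEL_NA,
    LABEL_NS,
    LABEL_S,
    PAIR_COLUMNS,
    PairStats,
)
from .expression_data import GroupKey, StudyDesign

# transition codes
NS_TO_S = "NS_to_S"
NA_TO_S = "NA_to_S"
S_TO_NS = "S_to_NS"
S_TO_NA = "S_to_NA"
S_TO_S_CHANGED = "S_to_S_changed"
S_S_UNCHANGED = "S_S_unchanged"
NS_NS = "NS_NS"
NA_NA = "NA_NA"
OTHER = "OTHER"

TRANSITION_CODES = (
    NS_TO_S,
    NA_TO_S,
    S_TO_NS,
    S_TO_NA,
    S_TO_S_CHANGED,
    S_S_UNCHANGED,
    NS_NS,
    NA_NA,
    OTHER,
)

DS1 = "DS1"
DS2 = "DS2"
DS3 = "DS3"
NO_SCENARIO = "none"
SCENARIOS = (DS1, DS2, DS3)

#: transitions that qualify a cell line for each differential scenario
DIFFERENTIAL_TRANSITIONS: dict[str, frozenset[str]] = {
    DS1: frozenset({NS_TO_S, NA_TO_S}),
    DS2: frozenset({S_TO_NS, S_TO_NA}),
    DS3: frozenset({S_TO_S_CHANGED}),
}

#: the three non-differential patterns accepted in Phenotype-B lines
NON_DIFFERENTIAL_TRANSITIONS = frozenset({NS_NS, NA_NA, S_S_UNCHANGED})


@dataclass(frozen=True)
class StrengthChangeTest:
    """Fisher r-to-z comparison of two correlations; applied only to S -> S."""

    alpha: float = 0.05
    method: str = "fisher-z"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def strength_change(
    r1: float, n1: int, r2: float, n2: int, alpha: float = 0.05
) -> bool:
    """True when the two correlations differ significantly (Fisher r-to-z).

    Two-sided z test on atanh(r1) - atanh(r2) with SE = sqrt(1/(n1-3) +
    1/(n2-3)). |r| = 1 is clamped to 1 - 1e-12, except that exactly equal
    correlations are always "unchanged".
    """
    if n1 < 4 or n2 < 4:
        raise ValueError("Fisher z needs at least 4 observations per group")
    if r1 == r2:
        return False
    clamp = 1.0 - 1e-12
    z1 = np.arctanh(np.clip(r1, -clamp, clamp))
    z2 = np.arctanh(np.clip(r2, -clamp, clamp))
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z1 - z2) / se)
    return bool(p < alpha)


def transition_code(
    label_control: str,
    label_treated: str,
    r_control: float = np.nan,
    n_control: int = 0,
    r_treated: float = np.nan,
    n_treated: int = 0,
    test: StrengthChangeTest = StrengthChangeTest(),
    lenient_nondiff: bool = False,
) -> str:
    """Map a (control label, treated label) combination to a transition code.

    Any combination involving EXCLUDED, and (in strict mode) mixed NS/NA
    across treatments, is OTHER — neither differential nor non-differential.
    With ``lenient_nondiff`` the NS/NA mixtures count as both-uncorrelated,
    i.e. as the NS_NS non-differential pattern.
    """
    lc, lt = label_control, label_treated
    if lc == LABEL_EXCLUDED or lt == LABEL_EXCLUDED:
        return OTHER
    if lt == LABEL_S:
        if lc == LABEL_NS:
            return NS_TO_S
        if lc == LABEL_NA:
            return NA_TO_S
        changed = strength_change(
            r_control, n_control, r_treated, n_treated, alpha=test.alpha
        )
        return S_TO_S_CHANGED if changed else S_S_UNCHANGED
    if lc == LABEL_S:
        return S_TO_NS if lt == LABEL_NS else S_TO_NA
    if lc == lt:
        return NS_NS if lc == LABEL_NS else NA_NA
    # mixed NS/NA
    return NS_NS if lenient_nondiff else OTHER


def transition(
    control: PairStats,
    treated: PairStats,
    test: StrengthChangeTest = StrengthChangeTest(),
    lenient_nondiff: bool = False,
) -> str:
    """Transition code for one gene pair from its per-group statistics."""
    if {control.gene_a, control.gene_b} != {treated.gene_a, treated.gene_b}:
        raise ValueError(
            f"mismatched pair: ({control.gene_a}, {control.gene_b}) vs "
            f"({treated.gene_a}, {treated.gene_b})"
        )
    return transition_code(
        control.label,
        treated.label,
        control.r,
        control.n_valid if control.n_valid else 0,
        treated.r,
        treated.n_valid if treated.n_valid else 0,
        test=test,
        lenient_nondiff=lenient_nondiff,
    )


@dataclass(frozen=True)
class ScenarioCall:
    """Scenario assignment and phenotype-filter verdict for one gene pair."""

    gene_a: str
    gene_b: str
    scenario: str  # DS1 / DS2 / DS3 / none
    transitions: Mapping[str, str]  # cell line -> transition code
    combination_key: str
    passes_filter: bool


def _combination_key(design: StudyDesign, transitions: Mapping[str, str]) -> str:
    lines = [p.cell_line for p in design.a_pairs] + [p.cell_line for p in design.b_pairs]
    return "|".join(f"{line}={transitions[line]}" for line in lines)


def _scenario_from_a_codes(a_codes: Sequence[str]) -> str:
    for ds, allowed in DIFFERENTIAL_TRANSITIONS.items():
        if all(code in allowed for code in a_codes):
            return ds
    return NO_SCENARIO


def call_scenario(
    gene_a: str,
    gene_b: str,
    transitions: Mapping[str, str],
    design: StudyDesign,
) -> ScenarioCall:
    """Combine per-cell-line transitions into a scenario call.

    ``transitions`` must hold one code per treatment pair in the design. The
    pair passes the phenotype filter when it has a scenario and every
    Phenotype-B line shows a non-differential pattern; with zero B lines the
    filter degenerates to the scenario requirement alone.
    """
    missing = [
        p.cell_line for p in design.treatment_pairs if p.cell_line not in transitions
    ]
    if missing:
        raise ValueError(f"missing transitions for cell line(s): {missing}")
    a_codes = [transitions[p.cell_line] for p in design.a_pairs]
    b_codes = [transitions[p.cell_line] for p in design.b_pairs]
    scenario = _scenario_from_a_codes(a_codes)
    passes = scenario != NO_SCENARIO and all(
        code in NON_DIFFERENTIAL_TRANSITIONS for code in b_codes
    )
    return ScenarioCall(
        gene_a=str(gene_a),
        gene_b=str(gene_b),
        scenario=scenario,
        transitions=dict(transitions),
        combination_key=_combination_key(design, transitions),
        passes_filter=passes,
    )


def _vector_transitions(
    control: pd.DataFrame,
    treated: pd.DataFrame,
    test: StrengthChangeTest,
    lenient_nondiff: bool,
) -> np.ndarray:
    lc = control["label"].to_numpy()
    lt = treated["label"].to_numpy()
    out = np.full(lc.size, OTHER, dtype=object)
    excl = (lc == LABEL_EXCLUDED) | (lt == LABEL_EXCLUDED)
    out[(lc == LABEL_NS) & (lt == LABEL_S)] = NS_TO_S
    out[(lc == LABEL_NA) & (lt == LABEL_S)] = NA_TO_S
    out[(lc == LABEL_S) & (lt == LABEL_NS)] = S_TO_NS
    out[(lc == LABEL_S) & (lt == LABEL_NA)] = S_TO_NA
    out[(lc == LABEL_NS) & (lt == LABEL_NS)] = NS_NS
    out[(lc == LABEL_NA) & (lt == LABEL_NA)] = NA_NA
    if lenient_nondiff:
        mixed = ((lc == LABEL_NS) & (lt == LABEL_NA)) | (
            (lc == LABEL_NA) & (lt == LABEL_NS)
        )
        out[mixed] = NS_NS
    ss = (lc == LABEL_S) & (lt == LABEL_S)
    if ss.any():
        r1 = control["r"].to_numpy()[ss]
        r2 = treated["r"].to_numpy()[ss]
        n1 = control["n_valid"].to_numpy()[ss]
        n2 = treated["n_valid"].to_numpy()[ss]
        clamp = 1.0 - 1e-12
        # effective n is the not-both-zero replicate count; pairs with fewer
        # than 4 effective points get an infinite SE, i.e. "unchanged"
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(
                1.0 / np.maximum(n1 - 3, 0) + 1.0 / np.maximum(n2 - 3, 0)
            )
            z = np.abs(
                np.arctanh(np.clip(r1, -clamp, clamp))
                - np.arctanh(np.clip(r2, -clamp, clamp))
            )
            p = np.where(np.isfinite(se), 2.0 * stats.norm.sf(z / se), 1.0)
        changed = (p < test.alpha) & (r1 != r2)
        codes = np.where(changed, S_TO_S_CHANGED, S_S_UNCHANGED)
        out[np.nonzero(ss)[0]] = codes
    out[excl] = OTHER
    return out


def call_scenarios_table(
    group_stats: Mapping[GroupKey, pd.DataFrame],
    design: StudyDesign,
    test: StrengthChangeTest = StrengthChangeTest(),
    lenient_nondiff: bool = False,
) -> pd.DataFrame:
    """Scenario calls for every gene pair, vectorized over the pair tables.

    ``group_stats`` maps each (cell line, treatment) group to the DataFrame
    produced by :func:`phenocoex.coexpression.classify_group`; all tables must
    list the same pairs in the same order. Returns one row per pair with a
    ``trans_<cell line>`` column per treatment pair, the scenario, the
    combination key, and the phenotype-filter verdict.
    """
    pairs_needed = [p for p in design.a_pairs + design.b_pairs]
    first = group_stats[pairs_needed[0].control_key]
    ref = first[["gene_a", "gene_b"]]
    for p in pairs_needed:
        for key in (p.control_key, p.treated_key):
            df = group_stats[key]
            if df.shape[0] != ref.shape[0] or not (
                df["gene_a"].to_numpy() == ref["gene_a"].to_numpy()
            ).all() or not (df["gene_b"].to_numpy() == ref["gene_b"].to_numpy()).all():
                raise ValueError(f"pair table for group {key} is not aligned")

    out = pd.DataFrame(
        {"gene_a": ref["gene_a"].to_numpy(), "gene_b": ref["gene_b"].to_numpy()}
    )
    a_codes = []
    b_codes = []
    for p in design.a_pairs:
        codes = _vector_transitions(
            group_stats[p.control_key], group_stats[p.treated_key], test, lenient_nondiff
        )
        out[f"trans_{p.cell_line}"] = codes
        a_codes.append(codes)
    for p in design.b_pairs:
        codes = _vector_transitions(
            group_stats[p.control_key], group_stats[p.treated_key], test, lenient_nondiff
        )
        out[f"trans_{p.cell_line}"] = codes
        b_codes.append(codes)

    scenario = np.full(out.shape[0], NO_SCENARIO, dtype=object)
    for ds, allowed in DIFFERENTIAL_TRANSITIONS.items():
        mask = np.ones(out.shape[0], dtype=bool)
        for codes in a_codes:
            mask &= np.isin(codes, list(allowed))
        scenario[mask] = ds
    nondiff_b = np.ones(out.shape[0], dtype=bool)
    for codes in b_codes:
        nondiff_b &= np.isin(codes, list(NON_DIFFERENTIAL_TRANSITIONS))
    out["scenario"] = scenario
    out["passes_filter"] = (scenario != NO_SCENARIO) & nondiff_b

    lines = [p.cell_line for p in design.a_pairs] + [p.cell_line for p in design.b_pairs]
    key = out[f"trans_{lines[0]}"].astype(str).radd(f"{lines[0]}=")
    for line in lines[1:]:
        key = key + "|" + out[f"trans_{line}"].astype(str).radd(f"{line}=")
    out["combination_key"] = key
    return out


def tally_combinations(calls: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    """Counts of passing pairs per (scenario, A-combination, B-pattern).

    For the canonical two-A-lines / one-B-line design, DS1 and DS2 each span
    4 A-combinations x 3 B-patterns = 12 conditions; all 24 keys are present
    even when zero. Other designs fall back to a tally keyed by the sorted
    multiset of A and B transition codes.
    """
    a_lines = [p.cell_line for p in design.a_pairs]
    b_lines = [p.cell_line for p in design.b_pairs]
    passing = calls[calls["passes_filter"]]

    if len(a_lines) == 2 and len(b_lines) == 1:
        rows = []
        grid = {
            DS1: [NS_TO_S, NA_TO_S],
            DS2: [S_TO_NS, S_TO_NA],
            DS3: [S_TO_S_CHANGED],
        }
        for ds, codes in grid.items():
            for c1 in codes:
                for c2 in codes:
                    for b in sorted(NON_DIFFERENTIAL_TRANSITIONS):
                        sub = passing[
                            (passing["scenario"] == ds)
                            & (passing[f"trans_{a_lines[0]}"] == c1)
                            & (passing[f"trans_{a_lines[1]}"] == c2)
                            & (passing[f"trans_{b_lines[0]}"] == b)
                        ]
                        rows.append(
                            {
                                "scenario": ds,
                                "a_combination": f"{a_lines[0]}={c1}|{a_lines[1]}={c2}",
                                "b_pattern": b,
                                "count": int(sub.shape[0]),
                            }
                        )
        return pd.DataFrame(rows)

    # generalized tally
    def multiset(row, lines):
        return "+".join(sorted(row[f"trans_{line}"] for line in lines))

    rows = []
    for (ds, a_key, b_key), sub in passing.groupby(
        [
            passing["scenario"],
            passing.apply(multiset, axis=1, lines=a_lines),
            (
                passing.apply(multiset, axis=1, lines=b_lines)
                if b_lines
                else pd.Series("", index=passing.index)
            ),
        ]
    ):
        rows.append(
            {"scenario": ds, "a_combination": a_key, "b_pattern": b_key, "count": len(sub)}
        )
    return pd.DataFrame(rows, columns=["scenario", "a_combination", "b_pattern", "count"])


@dataclass(frozen=True)
class FilterEffect:
    """What the phenotype filter removes: pair counts with and without it."""

    n_with: int
    n_without: int

    @property
    def n_extra(self) -> int:
        return self.n_without - self.n_with

    @property
    def pct_increase(self) -> float | None:
        """Percent increase from filtered to unfiltered, one decimal, half-up;
        undefined (None) when no pair passes the filter."""
        if self.n_with == 0:
            return None
        return round_half_up(100.0 * self.n_extra / self.n_with, 1)


def apply_filter_toggle(calls: pd.DataFrame) -> FilterEffect:
    """Compare the passing set against the unfiltered differential set.

    ``n_with`` counts pairs passing the phenotype filter; ``n_without`` counts
    pairs with any differential scenario regardless of the B-line patterns.
    The passing set is always a subset, so n_with <= n_without.
    """
    n_with = int(calls["passes_filter"].sum())
    n_without = int((calls["scenario"] != NO_SCENARIO).sum())
    return FilterEffect(n_with=n_with, n_without=n_without)


def filter_effect_from_counts(n_with: int, n_without: int) -> FilterEffect:
    """Filter-effect arithmetic from externally reported pair counts."""
    if n_with > n_without:
        raise ValueError("filtered count cannot exceed unfiltered count")
    return FilterEffect(n_with=n_with, n_without=n_without)
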