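"""Multi-round virtual-screening orchestration and energy bookkeeping.

The cascade mirrors the published workflow: a pharmacophore fit filter
(qfit strictly above 50), a topological fragment-similarity stage, an
external docking-score filter (docking score > 9 and consensus Cscore > 4)
and a rule-based ADME/T filter over predicted property tables.  Docking
scores and ADME properties are always *inputs* — produced by external
engines and web predictors — never computed here.

All inequality thresholds are strict, exactly as the criteria are
typeset.  Energies are kJ/mol throughout (grid fields elsewhere are
kcal/mol); the MM-PBSA binding free energy must satisfy the bookkeeping
identity ΔG_binding = ΔE_vdW + ΔE_ele + ΔG_PB + ΔG_SA, which doubles as a
consistency validator for ingested energy tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError, FormatError, ValidationError
from .fragments import FragmentRecord, cut_r_groups, topdist
from .pharmacophore import PharmacophoreModel, qfit_score

# ---------------------------------------------------------------------------
# rule-based property filter


@dataclass(frozen=True)
class Rule:
    """One ADME/T acceptance rule; all comparisons are strict."""
    prop: str
    op: str            # 'gt' | 'lt' | 'between' | 'eq'
    bound: object

    def holds(self, value) -> bool:
        if self.op == "gt":
            return value > self.bound
        if self.op == "lt":
            return value < self.bound
        if self.op == "between":
            lo, hi = self.bound
            return lo < value < hi
        if self.op == "eq":
            return value == self.bound
        raise ConfigError(f"unknown rule operator {self.op!r}")

    def describe(self) -> str:
        if self.op == "between":
            lo, hi = self.bound
            return f"{lo} < {self.prop} < {hi}"
        sym = {"gt": ">", "lt": "<", "eq": "=="}[self.op]
        return f"{self.prop} {sym} {self.bound}"


#: The published hit-selection criteria over pkCSM/SwissADME-style tables.
DEFAULT_ADME_RULES = (
    Rule("mw", "between", (150.0, 500.0)),
    Rule("tpsa", "between", (20.0, 130.0)),
    Rule("gi_absorption", "eq", "High"),
    Rule("bbb_permeant", "eq", "Yes"),
    Rule("cns_log_ps", "gt", -2.0),
    Rule("caco2", "gt", 0.9),
    Rule("hia", "gt", 90.0),
    Rule("cyp2d6_inhibitor", "eq", "No"),
    Rule("cyp3a4_inhibitor", "eq", "No"),
    Rule("herg_inhibitor", "eq", "No"),
    Rule("skin_sensitization", "eq", "No"),
    Rule("lipinski_violations", "eq", 0),
    Rule("synthetic_accessibility", "lt", 4.0),
)


@dataclass
class CascadeConfig:
    qfit_threshold: float = 50.0
    docking_score_min: float = 9.0
    cscore_min: float = 4.0
    topdist_max: float = 185.0
    min_heavy: int = 3
    adme_rules: tuple[Rule, ...] = DEFAULT_ADME_RULES
    stage_order: tuple[str, ...] = ("pharmacophore", "fragments", "score", "adme")

    def __post_init__(self):
        for value in (self.qfit_threshold, self.docking_score_min,
                      self.cscore_min, self.topdist_max):
            if not math.isfinite(value):
                raise ConfigError("cascade thresholds must be finite")


def adme_filter(records: pd.DataFrame, rules=DEFAULT_ADME_RULES
                ) -> tuple[list[str], list[tuple[str, str]]]:
    """Apply every rule; a record survives iff all hold.

    Returns (retained ids, rejection log) where the log names the first
    failing rule per rejected record.
    """
    if "id" not in records.columns:
        raise FormatError("property table lacks an 'id' column")
    for rule in rules:
        if rule.prop not in records.columns:
            raise ConfigError(f"rule references unknown property {rule.prop!r}")
    retained, rejected = [], []
    for _, row in records.iterrows():
        for rule in rules:
            if not rule.holds(row[rule.prop]):
                rejected.append((str(row["id"]), rule.describe()))
                break
        else:
            retained.append(str(row["id"]))
    return retained, rejected


def score_filter(scores: pd.DataFrame, docking_score_min: float = 9.0,
                 cscore_min: float = 4.0) -> list[str]:
    """Strict conjunction: docking_score > min and cscore > min."""
    for col in ("id", "docking_score", "cscore"):
        if col not in scores.columns:
            raise FormatError(f"score table lacks required column {col!r}")
    keep = (scores["docking_score"] > docking_score_min) & (scores["cscore"] > cscore_min)
    return [str(i) for i in scores.loc[keep, "id"]]


# ---------------------------------------------------------------------------
# MM-PBSA bookkeeping


@dataclass(frozen=True)
class EnergyComponents:
    """One complex's MM-PBSA decomposition, kJ/mol."""
    evdw: float
    eele: float
    gpb: float
    gsa: float
    gbind: float | None = None


def sum_binding_energy(evdw: float, eele: float, gpb: float, gsa: float) -> float:
    """ΔG_binding = ΔE_vdW + ΔE_ele + ΔG_PB + ΔG_SA (kJ/mol)."""
    parts = (evdw, eele, gpb, gsa)
    if not all(math.isfinite(v) for v in parts):
        raise DomainError("energy components must be finite")
    return float(sum(parts))


_ENERGY_COLS = ("dEvdw_kJmol", "dEele_kJmol", "dGpb_kJmol", "dGsa_kJmol")


def validate_energy_table(df: pd.DataFrame, tol: float = 0.01) -> pd.DataFrame:
    """Recompute ΔG_binding per row and flag rows violating the component sum.

    Adds ``dGbind_computed`` and, when the table declares its own
    ``dGbind_kJmol``, a boolean ``consistent`` column true when the two
    agree within ``tol`` kJ/mol.
    """
    for col in _ENERGY_COLS:
        if col not in df.columns:
            raise FormatError(f"energy table lacks column {col!r}")
    out = df.copy()
    out["dGbind_computed"] = [
        sum_binding_energy(*row) for row in df[list(_ENERGY_COLS)].itertuples(index=False)
    ]
    if "dGbind_kJmol" in df.columns:
        out["consistent"] = (out["dGbind_computed"] - df["dGbind_kJmol"]).abs() <= tol
    return out


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class StageResult:
    name: str
    n_in: int
    n_out: int
    rejected: list[tuple[str, str]] = dc_field(default_factory=list)


@dataclass
class CascadeReport:
    stages: list[StageResult]
    final_ids: list[str]

    def counts(self) -> list[int]:
        return [self.stages[0].n_in] + [s.n_out for s in self.stages] if self.stages else []


def run_cascade(library, *, pharm_model: PharmacophoreModel | None = None,
                fragment_queries: dict[str, FragmentRecord] | None = None,
                scores: pd.DataFrame | None = None,
                props: pd.DataFrame | None = None,
                config: CascadeConfig = CascadeConfig()) -> CascadeReport:
    """Run the configured stages in order over a molecule library.

    Fail-fast: every stage named in ``config.stage_order`` must have its
    inputs resolvable before any stage runs.  Stage counts are monotone
    non-increasing; per-record filters commute, so the final id set does
    not depend on the stage order.
    """
    molecules = {m.id: m for m in library}
    if not molecules:
        raise ValidationError("empty screening library")
    needs = {"pharmacophore": pharm_model, "fragments": fragment_queries,
             "score": scores, "adme": props}
    for stage in config.stage_order:
        if stage not in needs:
            raise ConfigError(f"unknown cascade stage {stage!r}")
        if needs[stage] is None:
            raise ConfigError(f"stage {stage!r} enabled but its input is missing")
        if stage in ("score", "adme") and len(needs[stage]) == 0:
            raise ConfigError(f"stage {stage!r} input table is empty")
    if "score" in config.stage_order:
        for col in ("id", "docking_score", "cscore"):
            if col not in scores.columns:
                raise FormatError(f"score table lacks required column {col!r}")
    if "fragments" in config.stage_order:
        for m in molecules.values():
            if "cut_bonds" not in m.meta:
                raise ConfigError(f"{m.id}: fragment stage needs declared cut bonds")

    current = list(molecules)
    stages = []
    for stage in config.stage_order:
        n_in = len(current)
        rejected: list[tuple[str, str]] = []
        if stage == "pharmacophore":
            survivors = []
            for mid in current:
                q = qfit_score(molecules[mid], pharm_model).qfit
                if q > config.qfit_threshold:
                    survivors.append(mid)
                else:
                    rejected.append((mid, f"qfit {q:.1f} <= {config.qfit_threshold}"))
        elif stage == "fragments":
            survivors = []
            for mid in current:
                frags = cut_r_groups(molecules[mid])
                reason = None
                for side, query in fragment_queries.items():
                    frag = frags[side]
                    if frag.heavy_atom_count < config.min_heavy:
                        reason = f"{side} below {config.min_heavy} heavy atoms"
                        break
                    dist = topdist(frag, query)
                    if dist > config.topdist_max:
                        reason = f"{side} topdist {dist:.0f} > {config.topdist_max:.0f}"
                        break
                if reason is None:
                    survivors.append(mid)
                else:
                    rejected.append((mid, reason))
        elif stage == "score":
            table = scores.set_index(scores["id"].astype(str))
            survivors = []
            for mid in current:
                if mid not in table.index:
                    rejected.append((mid, "no docking score"))
                    continue
                row = table.loc[mid]
                if (row["docking_score"] > config.docking_score_min
                        and row["cscore"] > config.cscore_min):
                    survivors.append(mid)
                else:
                    rejected.append((mid, "docking/cscore threshold"))
        else:  # adme
            subset = props[props["id"].astype(str).isin(current)]
            kept, rej = adme_filter(subset, config.adme_rules)
            missing = [(mid, "no property record") for mid in current
                       if mid not in set(props["id"].astype(str))]
            survivors = [mid for mid in current if mid in set(kept)]
            rejected = rej + missing
        stages.append(StageResult(stage, n_in, len(survivors), rejected))
        current = survivors
    return CascadeReport(stages=stages, final_ids=current)
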