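"""Drug-repurposing triage for genetically validated targets.

A gene becomes a prioritized target when it is both MR-significant
(BH q < 0.05) and colocalized (PP4 > 0.75).  Its drug candidates then pass
through the three-level inclusion gate — Level I specific action, Level II
established safety/efficacy, Level III regulatory approval — and a
direction-of-effect concordance check: risk-increasing expression calls for
inhibition, protective expression for activation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import ConsistencyError, VocabularyError
from .types import ACTION_TYPES, ColocResult, DrugCandidate, MrResult

_INHIBITING = {"inhibitor", "antagonist", "antibody"}
_ACTIVATING = {"agonist", "activator", "cofactor"}


@dataclass
class PrioritizedTarget:
    """A gene surviving both the MR-FDR and colocalization gates."""

    gene: str
    tissue: str
    mr: MrResult
    coloc: ColocResult
    risk_direction: str  # risk_increasing | protective
    candidates: list = field(default_factory=list)


def prioritize_targets(mr_results: Sequence[MrResult],
                       coloc_results: Sequence[ColocResult],
                       fdr: float = 0.05, pp4: float = 0.75,
                       tissue: str = "blood") -> list[PrioritizedTarget]:
    """Intersect MR-significant genes with colocalized genes.

    The risk direction is the sign of the MR beta (log-odds per SD of
    expression).  A coloc result for a gene absent from the MR table is a
    join inconsistency and raises.
    """
    mr_by_gene = {r.gene: r for r in mr_results}
    out = []
    for cres in sorted(coloc_results, key=lambda c: c.gene):
        mres = mr_by_gene.get(cres.gene)
        if mres is None:
            raise ConsistencyError(
                f"coloc result for {cres.gene} has no matching MR result")
        if mres.qval < fdr and cres.pp4 > pp4:
            direction = "risk_increasing" if mres.beta > 0 else "protective"
            out.append(PrioritizedTarget(gene=cres.gene, tissue=tissue,
                                         mr=mres, coloc=cres,
                                         risk_direction=direction))
    return out


def apply_inclusion_criteria(candidates: Sequence[DrugCandidate]
                             ) -> list[DrugCandidate]:
    """Set ``level_passed`` on each candidate and sort by it (descending),
    then drug name.

    Level 0: broad-spectrum action (fails Level I); 1: specific but safety
    or efficacy unestablished; 2: safe and efficacious but not approved;
    3: approved.
    """
    out = []
    for cand in candidates:
        if cand.broad_spectrum:
            level = 0
        elif not cand.safety_established:
            level = 1
        elif not cand.approved:
            level = 2
        else:
            level = 3
        cand.level_passed = level
        out.append(cand)
    return sorted(out, key=lambda c: (-c.level_passed, c.drug_name))


def direction_concordance(target: PrioritizedTarget,
                          candidate: DrugCandidate) -> str:
    """Does the drug's action oppose the genetically inferred risk direction?

    risk-increasing x inhibiting action -> concordant; protective x
    activating action -> concordant; opposite pairings -> discordant;
    action 'other' -> indeterminate.
    """
    action = candidate.action_type
    if action not in ACTION_TYPES:
        raise VocabularyError(
            f"unknown action_type {action!r}; allowed: {', '.join(ACTION_TYPES)}")
    if action == "other":
        return "indeterminate"
    inhibiting = action in _INHIBITING
    if target.risk_direction == "risk_increasing":
        return "concordant" if inhibiting else "discordant"
    return "discordant" if inhibiting else "concordant"


def attach_candidates(targets: Sequence[PrioritizedTarget],
                      drug_table: Sequence[DrugCandidate]
                      ) -> list[PrioritizedTarget]:
    """Attach each target's leveled drug candidates (per-tissue rows are kept
    separate; no cross-tissue reconciliation)."""
    by_gene: dict[str, list[DrugCandidate]] = {}
    for cand in drug_table:
        by_gene.setdefault(cand.gene, []).append(cand)
    for target in targets:
        target.candidates = apply_inclusion_criteria(
            by_gene.get(target.gene, []))
    return list(targets)
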