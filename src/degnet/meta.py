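"""Combine per-dataset DEG results across studies by set intersection.

Test datasets drive the per-class intersections (genes significant with
the *same* direction in every test analysis of a class) and the core
gene set; validation datasets drive the final-DEG filter and the
direction-concordance table.  No effect sizes are pooled: integration is
purely by membership and sign, mirroring the multi-cohort vote that a
Table-1/Table-2 style report encodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

UP, DOWN, BLANK = "Up", "Down", ""


@dataclass
class AnalysisResult:
    """One dataset's DE result for one comparison class."""

    dataset: str
    label: str  # MvsN / PvsN / MvsP
    result: pd.DataFrame  # moderated_t_test output (indexed by gene)

    @property
    def column(self) -> str:
        return f"{self.dataset}:{self.label}"


def intersect_class(deg_sets: list[dict[str, str]]) -> dict[str, str]:
    """Direction-consistent intersection of DEG sets for one class.

    A gene survives only if it appears in *every* set with the same
    direction; direction-discordant genes are excluded.
    """
    if not deg_sets:
        raise ValueError("need at least one DEG set to intersect")
    common = dict(deg_sets[0])
    for degs in deg_sets[1:]:
        common = {g: d for g, d in common.items() if degs.get(g) == d}
    return common


def final_deg_set(
    class_intersections: dict[str, dict[str, str]],
    validation_results: list[AnalysisResult],
    presence_cut: float = 0.2,
    allow_one_discordant: bool = False,
) -> set[str]:
    """Validate the union of class intersections against validation cohorts.

    A union gene is dropped when a validation analysis of a matching
    class measures it with ``|logFC| >= presence_cut`` in the direction
    *opposite* to the test consensus.  Cells below the cutoff, or genes
    not measured in a validation dataset, never penalize (they are the
    blank cells of an otherwise concordant row).  With
    ``allow_one_discordant=True`` a single opposing cell is tolerated.
    """
    max_opposing = 1 if allow_one_discordant else 0
    final: set[str] = set()
    union: dict[str, dict[str, str]] = {}
    for label, degs in class_intersections.items():
        for gene, direction in degs.items():
            union.setdefault(gene, {})[label] = direction
    for gene, directions in union.items():
        opposing = 0
        for analysis in validation_results:
            consensus = directions.get(analysis.label)
            if consensus is None or gene not in analysis.result.index:
                continue
            lfc = float(analysis.result.loc[gene, "logFC"])
            if abs(lfc) < presence_cut:
                continue
            observed = UP if lfc > 0 else DOWN
            if observed != consensus:
                opposing += 1
        if opposing <= max_opposing:
            final.add(gene)
    logger.info("final DEG filter: %d/%d union genes validated",
                len(final), len(union))
    return final


def select_core_genes(
    class_intersections: dict[str, dict[str, str]],
    validated_final: set[str],
    user_list: list[str] | None = None,
) -> set[str]:
    """Core gene set for network proximity scoring.

    Default: the metastatic-vs-primary intersection restricted to the
    validated final DEGs.  A user-supplied list overrides verbatim.  An
    empty core set is an error (the Dj score is undefined without one).
    """
    if user_list is not None:
        core = set(user_list)
    else:
        core = set(class_intersections.get("MvsP", {})) & validated_final
    if not core:
        raise ValueError("core gene set is empty; Dj scoring undefined")
    return core


def direction_table(
    results: list[AnalysisResult],
    genes: list[str],
    report_cut: float = 0.2,
) -> pd.DataFrame:
    """Per-gene Up/Down calls across analyses; |logFC| < report_cut is blank.

    Columns are ``dataset:label`` analysis identifiers; genes absent
    from a dataset get a blank cell.  A cell at exactly the cutoff is
    reported (>= rule).
    """
    table = pd.DataFrame(BLANK, index=pd.Index(genes, name="gene"),
                         columns=[r.column for r in results])
    for analysis in results:
        present = [g for g in genes if g in analysis.result.index]
        lfc = analysis.result.loc[present, "logFC"]
        calls = lfc.map(lambda x: UP if x > 0 else DOWN)
        calls[lfc.abs() < report_cut] = BLANK
        table.loc[present, analysis.column] = calls
    return table


def classify_concordance(row: pd.Series | list[str]) -> str:
    """Classify a direction-table row: uniform / one_discordant / heterogeneous.

    Blank cells are ignored.  ``uniform``: every non-blank cell agrees.
    ``one_discordant``: exactly one cell disagrees with a strict
    majority.  Anything else (including an even split) is
    ``heterogeneous``; an all-blank row is ``undefined``.
    """
    cells = [c for c in row if c != BLANK]
    if not cells:
        return "undefined"
    n_up = sum(c == UP for c in cells)
    n_down = len(cells) - n_up
    minority = min(n_up, n_down)
    if minority == 0:
        return "uniform"
    if minority == 1 and max(n_up, n_down) >= 2:
        return "one_discordant"
    return "heterogeneous"


def concordance_report(table: pd.DataFrame) -> pd.DataFrame:
    """Direction table plus a concordance class column per gene."""
    out = table.copy()
    out["concordance"] = [classify_concordance(table.loc[g]) for g in table.index]
    return out
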