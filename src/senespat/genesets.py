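"""Named senescence hallmark gene sets and their control pool.

The scoring workflow uses three multi-hallmark senescence lists plus seven
individual hallmark programs (cell-cycle arrest, SASP, apoptosis
resistance, DNA-damage response, cell-surface markers, lysosomal content,
and p53 targets). Genes outside every list form the control pool from
which a fixed control set (nominally 2,000 genes) is sampled once per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

INDIVIDUAL_HALLMARKS = (
    "cell_cycle_arrest",
    "sasp",
    "apoptosis_resistance",
    "dna_damage_response",
    "cell_surface_markers",
    "lysosomal_content",
    "p53_targets",
)

MULTI_HALLMARKS = ("multi_a", "multi_b", "multi_c")


@dataclass
class HallmarkGeneSets:
    """Hallmark gene lists, the non-member pool, and the fixed control set."""

    multi: dict[str, list[str]]
    individual: dict[str, list[str]]
    control_pool: list[str]
    control_set: list[str] = field(default_factory=list)

    @property
    def all_lists(self) -> dict[str, list[str]]:
        return {**self.multi, **self.individual}

    def members(self) -> set[str]:
        """Union of genes across every hallmark list."""
        out: set[str] = set()
        for genes in self.all_lists.values():
            out.update(genes)
        return out

    def validate(self) -> None:
        if len(self.individual) != len(INDIVIDUAL_HALLMARKS):
            raise ValueError("expected 7 individual hallmark lists")
        if len(self.multi) != len(MULTI_HALLMARKS):
            raise ValueError("expected 3 multi-hallmark lists")
        members = self.members()
        if members & set(self.control_pool):
            raise ValueError("control pool overlaps a hallmark list")
        if set(self.control_set) & members:
            raise ValueError("control set overlaps a hallmark list")


def read_gene_lists(directory) -> dict[str, list[str]]:
    """Read one-gene-per-line text files; the stem names the list."""
    from pathlib import Path

    out = {}
    for path in sorted(Path(directory).glob("*.txt")):
        genes = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
        out[path.stem] = genes
    return out


def write_gene_lists(lists: dict[str, list[str]], directory) -> None:
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for name, genes in lists.items():
        (d / f"{name}.txt").write_text("\n".join(genes) + "\n")
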