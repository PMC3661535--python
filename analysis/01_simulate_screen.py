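#!/usr/bin/env python
"""Generate the synthetic expression screen used by the downstream analyses.

Draws the default planted scenario — 400 genes, 7 structures in three
germ-layer-like groups, 5% per-stage detection dropout — and writes the
annotation, gene-metadata and pathway-map TSVs plus the ground-truth JSON
under results/sim/.
"""

import sys
from pathlib import Path

from swepatlas.annotation_core import annotation_tsv, gene_meta_tsv
from swepatlas.synthetic import SimConfig, generate, planted_pathway_map

OUT = Path("results/sim")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=SEED)
    matrix, truth = generate(cfg)
    (OUT / "screen.annotations.tsv").write_text(annotation_tsv(matrix))
    (OUT / "screen.gene_meta.tsv").write_text(gene_meta_tsv(matrix.gene_meta))
    pm = planted_pathway_map(cfg)
    rows = ["gene_id\tmajor_category\tspecific_pathway"]
    for g in sorted(pm.major):
        for c in sorted(pm.major[g]):
            sp = sorted(s for s in pm.specific.get(g, ()) if s.startswith(c))
            rows.append(f"{g}\t{c}\t{sp[0] if sp else ''}")
    (OUT / "screen.pathways.tsv").write_text("\n".join(rows) + "\n")
    (OUT / "screen.truth.json").write_text(truth.to_json())

    n_roles = {r: list(truth.gene_role.values()).count(r) for r in
               ("restricted", "ubiquitous", "silent")}
    print(f"seed {SEED}: {len(matrix)} records over {len(matrix.structures)} structures")
    print(f"gene roles: {n_roles} (of {cfg.n_genes_total} total)")
    print(f"wrote annotation/metadata/pathway TSVs and truth JSON to {OUT}/")


if __name__ == "__main__":
    main()
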