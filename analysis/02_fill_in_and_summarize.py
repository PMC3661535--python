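#!/usr/bin/env python
"""Parse the simulated screen, apply the fill-in correction and tabulate the
per-class summary (investigated / tissue-restricted / ubiquitous).

Reads results/sim/, writes the corrected annotations and the class-summary
table under results/.
"""

from pathlib import Path

from swepatlas.annotation_core import (
    annotation_tsv,
    apply_fill_in,
    parse_annotations,
    parse_gene_meta,
    summarize_classes,
)

SIM = Path("results/sim")
OUT = Path("results")


def main() -> None:
    meta = parse_gene_meta(SIM / "screen.gene_meta.tsv")
    matrix = parse_annotations(SIM / "screen.annotations.tsv", gene_meta=meta)
    filled, n_corrected = apply_fill_in(matrix)
    print(
        f"{len(filled)} records; fill-in corrected {n_corrected} "
        f"({100 * n_corrected / len(filled):.1f}%) non-contiguous observations"
    )
    (OUT / "screen.filled.tsv").write_text(annotation_tsv(filled))

    summary = summarize_classes(filled)
    frame = summary.to_frame()
    print(frame.to_string(index=False))
    frame.to_csv(OUT / "class_summary.tsv", sep="\t", index=False)
    print(
        f"tissue-restricted overall: {summary.total.pct_tissue_restricted}% "
        f"of {summary.total.n_investigated} genes investigated"
    )


if __name__ == "__main__":
    main()
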