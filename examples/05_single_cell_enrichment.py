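"""Single-cell enrichment of a bulk-derived peak set.

Scores each synthetic cell for a target peak set against
accessibility-matched backgrounds, then runs the one-vs-rest mixed model
(z ~ celltype + (1|sample)) per cell type and developmental stage group.
"""

import chromdomains as cd

cfg = cd.SimConfig(n_cells=800, n_cell_types=4,
                   celltype_signal_fraction=0.1, seed=7)
peaks, matrix, truth = cd.simulate_bulk(cfg)
cells = cd.simulate_single_cell(cfg, truth, peaks)

target = truth.celltype_signal_peaks["type_1"]
scores = cd.cell_set_zscores(cells, target, B=50, seed=7,
                             target_id="type1_signal")
print(f"scored {cells.n_obs} cells against {len(target)} target peaks "
      f"(B=50 matched backgrounds)")
for t in sorted(cells.obs["cell_type"].unique()):
    mask = (cells.obs["cell_type"] == t).to_numpy()
    print(f"  mean z in {t}: {scores.z[mask].mean():+.2f}")

scan = cd.enrichment_scan(scores, cells)
print(scan.to_string(index=False))
# The planted type shows elevated z and a positive, significant mixed-model
# coefficient; other types stay at baseline after BH correction.
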