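# kinforge

A pedigree-graph toolkit for genealogical analysis: tolerant GEDCOM I/O, an
exhaustive relationship-path calculator, shared-centimorgan relationship
probabilities, a placement-hypothesis engine for locating an unknown
individual from DNA-match evidence, mortality inference and living-person
redaction, surname connectors across disconnected trees, deterministic
hierarchical layout with grid-tile aggregation, and seeded synthetic pedigree
generators so everything is testable without external data.

## Library overview

| Module | What it does |
| --- | --- |
| `kinforge.gedcom_io` | Tolerant parsing of GEDCOM 5.5/5.5.1 (lenient 7.0 headers), normalization to canonical 5.5.1, writing, and round-trippable workspace extensions (`_POS`, `_OMAPS`: positions, zoom, viewport, bookmarks, history, DNA matches). |
| `kinforge.pedigree_graph` | The bipartite individual/family graph, half-generation U/D/S traversal moves, connected components, cycle detection. |
| `kinforge.relationship` | Common-ancestor discovery, endogamy-aware enumeration of all up-then-down kinship paths (half relationships included), canonical kinship naming, MRCA path subgraphs with DOT/SVG export. |
| `kinforge.cm_model` | Bundled shared-cM calibration table (CSV, swappable), per-class posteriors for an observed shared-cM amount, geometric-mean evidence combination, consistency quality factor. |
| `kinforge.ggps` | The placement engine: traces verified prefixes of plausible relationship move strings from each match, intersects exit events on (node, remaining half-edges), and ranks hypotheses by `(W_eff + alpha) / (P_combined * P_t * Q_factor)` (lower is better). |
| `kinforge.curation` | Mortality inference (death records; descendants aged 85+ within five generations; 110-year age cap), deny-by-default redaction as a view, Jaro-Winkler surname connectors. |
| `kinforge.layout_view` | Deterministic layout: components -> longest-path layering -> two-phase anchoring for components over 150 nodes (600/2000 px family grid) -> seeded force refinement inside layer bands; tile aggregation activates above 500 visible nodes. |
| `kinforge.synthetic_fixtures` | Seeded pedigree simulator (Poisson offspring, remarriage, cousin marriage, missing parents) and full placement test cases with ground-truth manifests. |

```python
from kinforge import parse_gedcom, build_graph, run_ggps, Match

doc, report = parse_gedcom(open("tree.ged", "rb").read())
graph = build_graph(doc)
hypotheses = run_ggps(graph, [Match("@I12@", 430.0), Match("@I31@", 115.0)])
for h in hypotheses[:3]:
    print(h.node_v, h.remaining_moves_r, h.score)
```

## CLI

```bash
kinforge convert in.ged -o out.ged --report report.json   # normalize to 5.5.1
kinforge relate tree.ged @I1@ @I2@ --all-paths            # relationship paths
kinforge mrca tree.ged @I1@ @I2@ @I3@ -o mrca.svg         # shared-ancestor diagram
kinforge prob --cm 115                                    # posterior probabilities
kinforge ggps tree.ged --matches matches.tsv -o hyps.json # placement hypotheses
kinforge infer-living tree.ged --year 2026 -o status.tsv
kinforge redact tree.ged -o redacted.ged
kinforge surnames tree.ged --threshold 0.9 -o links.tsv
kinforge layout tree.ged --seed 1 -o laid.ged             # writes _POS extensions
kinforge tiles laid.ged --viewport 0,0,8000,8000 --tile-size 2048 -o tiles.json
kinforge simulate --seed 1 -o case_dir/                   # synthetic test case
```

`matches.tsv` is a two-column TSV (`individual_id`, `shared_cM`).

## Calibration table

`src/kinforge/data/shared_cm_calibration.csv` holds binned relative
likelihoods per relationship class (`class,half,bin_lo,bin_hi,likelihood`,
bins covering 0-3600 cM). Classes whose total-cM sharing is empirically
indistinguishable (e.g. half first cousin / first cousin once removed /
great-great-grandparent) carry identical rows; posteriors are reported per
sharing group under the familiar cousin-line label. The table is regenerated
by `python scripts/build_calibration.py` from published sharing averages and
can be replaced with any CSV in the same format (`--table` on the CLI).

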