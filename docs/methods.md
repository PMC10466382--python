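# Methods

## Model and procedure

consite treats a family of homologous protein chains as repeated noisy
observations of one structure. Species that matter — catalytic metals,
structural waters, cofactor atoms — recur at (nearly) the same position
relative to the fold, so after mapping every homolog into the query's
coordinate frame their heteroatoms pile up where the family conserves
them, while incidental solvent and crystallization additives scatter.

The pipeline has four stages:

1. **Homolog selection.** A sequence-identity cluster file (one
   whitespace-separated cluster of entity/chain identifiers per line, the
   RCSB dialect at cutoffs 30/40/50/70/90/95/100%, or a custom file of
   the same shape) names the family. Entity tokens (`PDBID_n`) expand to
   the polymer chains of the corresponding local file; explicit
   `PDBID.C` tokens name a chain directly. The optional
   one-chain-per-entry policy keeps the alphabetically first chain of
   each entry, which avoids over-counting crystallographic copies.
2. **Superposition.** Global sequence alignment (Needleman–Wunsch,
   BLOSUM62, gap open −10, extend −0.5) gives a residue correspondence;
   a Kabsch least-squares fit of matched Cα atoms gives the rigid
   transform; up to 5 refinement cycles drop pairs deviating more than
   2.0 Å and refit. Only Cα atoms enter the fit — side chains of mutated
   homologs would otherwise bias it. *Local mode* first extracts every
   query residue with an atom within `local_radius` (default 12 Å,
   inclusive) of the selected heteroatom group, keeps those residues
   whole, and uses the fragment as the fixed side; the resulting
   transform still applies to the whole homolog.
3. **Pooling and clustering.** Every HETATM of the query (untransformed)
   and of each superposed homolog (transformed) is typed
   `RESNAME-ATOMNAME` and pooled per species. Per species, DBSCAN runs on
   the 3D coordinates at ε = 0.9 Å for every minimum-neighbor value
   *n* = 1 … *N*<sub>sp</sub>; each distinct member set found anywhere in
   the sweep becomes one candidate cluster, recorded with the largest *n*
   that still returns it (a tightness indicator).
4. **Scoring and analysis.** Conservation = members / *N*<sub>sp</sub>,
   where *N*<sub>sp</sub> counts the query plus every homolog that
   actually superposed (members that fail — e.g. too few matched
   residues — are logged, skipped, and excluded from the denominator).
   The cluster position is the arithmetic mean of its members;
   within-cluster RMSD (root-mean-square member-to-centroid distance)
   measures tightness; d<sub>c</sub> — centroid to a native reference
   atom — scores a prediction against a holo structure. Contact lists
   give, per query residue, the closest atom within 3.5 Å of the
   centroid (up to 8 residues, a coordination-sphere scale).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `eps` | 0.9 Å | DBSCAN neighborhood radius; about the positional scatter of a conserved ion across well-superposed homologs |
| `n_sweep_max` | *N*<sub>sp</sub> | ceiling of the min-neighbor sweep and conservation denominator |
| `gap_open` / `gap_extend` | −10 / −0.5 | affine gap penalties with BLOSUM62, standard for global protein alignment |
| `refine_cycles` / `reject_cutoff` | 5 / 2.0 Å | align-style iterative outlier rejection |
| `local_radius` | 12 Å | residue-selection radius around the binding-site group in local mode |
| `min_conservation_report` | 0.0 | reporting floor; even weakly conserved clusters can be meaningful, so nothing is hidden by default |
| contact `cutoff` / `max_hits` | 3.5 Å / 8 | coordination-sphere scale for the contact table |

Conservation is kept as an exact ratio internally and displayed rounded
to two decimals, half-up (16/18 → 0.89). Coordinates are Å throughout.

## Numerical and design choices

- **DBSCAN determinism.** Textbook DBSCAN assigns border points reachable
  from two clusters to whichever cluster is expanded first, which depends
  on input order. Here points are ranked by coordinates and a border
  point joins the cluster of its lowest-ranked core neighbor, making
  labels a pure function of the point set. Core rule: ≥ *n* neighbors
  within ε, self included (the scikit-learn convention). This is why the
  clusterer is implemented in-package (KD-tree neighborhoods + BFS)
  instead of calling scikit-learn, which remains an independent
  cross-check in the tests.
- **Sweep deduplication** keys on the exact member set under the
  canonical point ordering, not on centroids, so near-coincident clusters
  at different *n* never merge by accident.
- **Conservation above 1.** The ratio deliberately does not deduplicate
  multiple contributions from one chain (two waters of one homolog in one
  cluster), so values above 1 are possible; the reported
  `distinct_sources` count exposes such cases.
- **Alt-locs** resolve to the highest-occupancy conformer (ties: first in
  file); multi-model files use MODEL 1 only — rigid superposition assumes
  one coordinate set per chain. Hydrogens in heteroatom groups are typed
  like any atom and simply form their own species.
- **Parsing** delegates to gemmi, with a strict column-validation pass on
  top: gemmi silently reads malformed coordinate fields as 0.0, which
  would corrupt a superposition without a trace, so consite raises a
  parse error naming the line instead. Nonstandard polymer residues map
  to 'X' for alignment.
- **Degenerate fits** (fewer than 3 pairs, collinear point sets) are
  rejected with explicit errors; the refinement keeps its last valid fit
  when rejection would leave fewer than 3 pairs.
- **Ties in sorting.** Clusters order by conservation (descending), then
  species label, then centroid lexicographically; report member rows by
  source chain then coordinates. Reports are byte-identical across
  reruns.
- **Backend contract.** Any callable with the signature of
  `superpose_whole` can replace the built-in method (e.g. wrappers around
  external structure aligners); only the built-in method ships.

## The synthetic benchmark

`consite.synthetic` generates families with exact ground truth: an ideal
α-helical Cα trace (rise 1.5 Å, 100°/residue, radius 2.3 Å → 3.8 Å Cα
spacing) with a random sequence; per homolog, residue substitutions at a
set rate, per-coordinate Gaussian noise (`ca_noise`, default 0.3 Å),
optionally a coherent displacement of the region distal to the first
planted site (ramping to `distal_distortion` at the chain end — emulating
homologs that match only near the binding site), planted heteroatoms with
per-coordinate jitter, uniform decoy heteroatoms, and a recorded random
rigid transform. `n_members` counts the whole family including the query,
so it equals *N*<sub>sp</sub> when everything superposes and a site with
presence *p* has ideal conservation exactly *p*. The query is apo by
default; `apo_query=False` makes it a holo query that always carries each
site (required for local mode, which needs a site group in the query).
Random streams are split per member and per purpose, so e.g. adding
decoys changes no transform, and written families are byte-identical per
seed.

What the benchmark does *not* emulate: real secondary-structure
diversity, side chains, correlated (non-isotropic) coordinate error,
crystal contacts, occupancy/disorder in heteroatoms, and genuinely
non-rigid conformational change (the distal distortion is a smooth
surrogate). Passing the end-to-end tests therefore demonstrates that the
machinery — correspondence, fitting, pooling, clustering, scoring — is
correct and well-calibrated at realistic noise scales, not that any
particular biological family will yield a given conservation.

Problem sizes used in the test suite (families of 8–20 chains of 40–60
residues, 20-trial statistical checks) were chosen as the smallest at
which the statistical properties under test are stable.

## Known limitations

- PDB fixed-column input only; no mmCIF/PDBx.
- Single-conformer, single-model view of each chain.
- Rigid-body superposition: domain motions between homologs must be
  handled by local mode around the site of interest.
- Entity tokens resolve to *all* chains of a local file, since the
  entity-to-chain mapping of the RCSB cluster dialect is not available
  offline; use explicit `PDBID.C` tokens when that matters.
- No hydrogen-bond geometry or coordination-geometry classification; the
  contact table reports distances only.
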