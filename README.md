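# consite

**consite** detects conserved heteroatom sites — metal ions, structural
waters, cofactor atoms — in a protein structure by exploiting its homologs.
It is aimed at structural biologists and modellers who have an *apo*
structure (or a model) and want to know where the family puts its zinc,
its catalytic waters, or its heme iron, without a docking run or a web
service: all inputs are local PDB files.

## The idea

Given a query chain and a set of homologous chains (taken from a
sequence-identity cluster file in the RCSB dialect, or any custom file of
the same shape):

1. **Superpose** every homolog onto the query. The built-in method aligns
   the sequences globally (Needleman–Wunsch, BLOSUM62, affine gaps
   −10/−0.5), fits the matched Cα pairs by least squares (Kabsch), and
   iteratively rejects pairs deviating by more than 2 Å and refits. A
   *local* mode fits only the query residues within a radius (default
   12 Å) of a chosen binding-site group, which sharpens predictions
   around that site when distal regions diverge.
2. **Pool** every HETATM of every superposed chain in the query's
   coordinate frame, typed by species as `RESNAME-ATOMNAME`
   (`ZN-ZN`, `HOH-O`, `HEC-FE`, ...).
3. **Cluster** each species' point cloud with 3D DBSCAN (ε = 0.9 Å),
   sweeping the minimum-neighbor parameter *n* from 1 to *N*<sub>sp</sub>,
   the number of superimposed chains (query included).
4. **Score** every cluster by its *conservation*

   conservation = (number of cluster members) / *N*<sub>sp</sub>,

   so a cluster of 16 zinc ions from 18 superposed chains reports 0.89.
   High conservation flags a position occupied by the same species across
   the family — the signature of a functional site.

Reports list each cluster's centroid (the predicted site position),
conservation, distinct source chains, within-cluster RMSD, and the
nearest query residues with contact distances.

## Worked example

The package ships a synthetic-family generator used throughout the tests:
it builds a helical query chain and 19 homologs (mutated, noised, rigidly
scattered), plants a zinc site 12 Å up the helix axis in 18 of the 20
chains (σ = 0.2 Å jitter), and salts each homolog with 3 random decoy
zincs. The query itself is apo.

```python
import consite as cs
spec = cs.FamilySpec(
    n_members=20, base_length=60, ca_noise=0.3, mutation_rate=0.1,
    planted_sites=(cs.PlantedSite("ZN-ZN", (0.0, 0.0, 12.0), 0.2, 0.9),),
    decoys_per_member=3, seed=11)
cs.write_family(cs.make_family(spec), "family")
```

```sh
$ consite --query family/QRY.pdb --homologs family/clusters.txt \
          --structures-dir family --out results
superposed 19 of 19 homolog chains (N_sp = 20)
found 58 clusters; report: results/clusters.tsv
```

The top of the report:

```text
# cluster_id  species  conservation  distinct_sources  n_members  max_min_neighbors  centroid_x ...
1             ZN-ZN    0.90          18                18         18                 0.088  -0.043  11.936 ...
```

The top cluster holds the 18 planted zincs — conservation 0.90, centroid
0.12 Å from the planted position (0, 0, 12) — while all 57 decoys end up
in single-member clusters at conservation 0.05. The contacts table names
the coordinating residues:

```text
1   A   LEU   9   CA   2.330134745150836
1   A   ALA   8   CA   2.6293060501779757
```

Local mode around a site present in the query works the same way:

```sh
consite --query family/QRY.pdb --homologs family/clusters.txt \
        --structures-dir family --mode local --site "ZN A 1001" \
        --radius 12 --out results_local
```

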