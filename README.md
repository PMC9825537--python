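# quatclust

Interface-based comparison and clustering of protein quaternary-structure
assemblies across independent experiments.

## The problem

The biologically relevant oligomeric form of a protein is often ambiguous in
crystal structures: several assemblies can be carved out of one crystal
lattice, and deposited annotations (author, PISA, EPPIC) disagree for a
substantial fraction of entries. Replication is strong evidence — if the same
assembly appears in many *independent* experiments (distinct crystal forms,
cryo-EM or NMR structures) of the same or homologous proteins, it is much more
likely to be the functional form. `quatclust` implements this
evidence-by-replication analysis for people working on quaternary-structure
annotation, benchmarking of assembly predictors, or curation of oligomeric
state for a protein family.

## The method

1. **Interfaces.** Two chains form an interface when they have at least ten
   pairs of Cβ atoms (Cα for glycine) within 12 Å and at least one heavy-atom
   contact within 5 Å, or at least five heavy-atom contacts within 5 Å.
2. **Q score.** Two interfaces are compared in a shared homologous coordinate
   (Pfam HMM match states, or pairwise-alignment columns) as

       Q = Σ_{p ∈ P₁∩P₂} w(p) / |P₁ ∪ P₂|

   over their contacting residue-pair sets P₁, P₂ — a (optionally
   distance-weighted, w = exp(−Δd²/2σ²)) Jaccard index.
3. **Unique connecting interfaces.** Within one assembly, interfaces are
   clustered by single linkage at Q ≥ 0.75; walking the clusters in
   descending surface-area order, representatives are kept until their member
   interfaces connect every chain. An ideal *Cn* ring reduces to one
   connecting interface, an ideal *D2* tetramer to two (one within and one
   between the dimers).
4. **Binary similarity.** Two assemblies of the same assembly Pfam
   architecture, stoichiometry and point-group symmetry are the same iff the
   connecting interfaces of each are all present among the unique interfaces
   of the other: S = S₁₂ × S₂₁ ∈ {0, 1}. Symmetry of heteromers whose chains
   share one Pfam architecture is the *pseudo*-symmetry (an A3B3 hexamer of
   two alternating rings is C3 on exact entities but D3 with architecture
   interchange); an internal superposition-based detector assigns Cn/Dn
   labels.
5. **Crystal forms and clusters.** Entries of one architecture group count as
   one independent experiment (crystal form, CF) when they share a space
   group and all six cell parameters within 5%; each EM/NMR entry is its own
   CF. Assemblies are clustered by single linkage over S = 1 within each
   (architecture, stoichiometry, symmetry) cell. Per cluster and per UniProt,
   **R_CF_UNPclus** = (CFs of that protein in the cluster) / (CFs of that
   protein in the whole corpus) measures how consistently the assembly is
   observed — e.g. 5 of 7 crystal forms gives 0.71.

Everything runs on synthetic ideal oligomers generated by
`quatclust.fixtures`, so no structure downloads are needed for tests or
demos.

## Worked example

Generate the built-in toy corpus — seven entries of one synthetic Pfam
architecture containing a shared C2 dimer, two incompatible D2 tetramers
built on that dimer, an EM entry, and one entry with a disconnected candidate
assembly — then cluster it:

```sh
$ quatclust fixtures demo --seed 0
toy corpus written to demo
$ quatclust cluster demo -o demo_out
INFO quatclust: excluding E007:asm2: assembly components are not connected
entries: 7  clusters: 3
report: demo_out/report.json
$ column -t demo_out/clusters.tsv | cut -c1-100
group   cluster_id  arch     stoichiometry  symmetry  n_cfs  n_unps  n_entries  r_cf_unpclus  PDB
(Tmpl)  0           (Tmpl)2  A2             C2        6      6       7          1.00          2
(Tmpl)  1           (Tmpl)4  A4             D2        2      2       3          1.00          3
(Tmpl)  2           (Tmpl)4  A4             D2        2      2       2          1.00          2
```

The shared dimer forms one A2 cluster spanning all seven entries and all six
crystal forms (E001/E002 share a crystal form, so 7 entries → 6 CFs); the two
tetramer types form two disjoint A4/D2 clusters; every cluster holds all of
its proteins' corpus crystal forms, so R_CF_UNPclus = 1.00. The disconnected
candidate of entry E007 is excluded and logged. Per-structure queries work
too:

```sh
$ quatclust symmetry demo/E001.cif
strict_entity: D2 (mean rmsd 0.00 Å)
pseudo_by_arch: D2 (mean rmsd 0.00 Å)
stoichiometry: A4
```

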