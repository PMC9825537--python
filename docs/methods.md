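# Methods

## Model and procedure

`quatclust` treats the determination of a biological assembly as a
replication problem: an oligomeric arrangement observed in many independent
experiments of homologous proteins is likely functional. The unit of
evidence is the *crystal form* (CF): a maximal single-linkage group of X-ray
entries of one Pfam-architecture group sharing a space group and unit cell
(each of the six parameters within 5%, relative to the larger value); every
cryo-EM or NMR entry is its own CF. Repeated depositions of the same crystal
therefore count once.

An assembly is characterised entirely by its chain–chain interfaces, not by
global structure alignment:

- **Interface criterion.** ≥10 representative-point pairs within 12 Å *and*
  ≥1 heavy-atom contact within 5 Å, *or* ≥5 heavy-atom contacts within 5 Å.
  The representative point is Cβ, with Cα substituted for glycine and for
  residues lacking a Cβ. Hydrogens are ignored; for alternate conformations
  the highest-occupancy conformer is kept (ties broken alphabetically by
  altloc).
- **Q score.** The contact-pair sets of two interfaces, projected into a
  shared homologous coordinate, are compared as a Jaccard index; in
  distance-weighted mode each common pair contributes
  `exp(−Δd²/(2σ²))` with σ = 3 Å, where Δd is the difference of the pair's
  representative-point distances in the two interfaces. Plain Jaccard
  weighting is the default and reference behaviour (it guarantees
  Q(A, A) = 1 exactly; the distance-weighted value is never larger). Within
  one entry the shared coordinate is the author numbering itself; across
  entries it is the Pfam HMM match-state column from the supplied assignment
  table, or a global pairwise alignment (match 1, mismatch −1, gap open −10,
  extend −0.5) when no table is available. For interfaces whose two sides
  have the same chain architecture the orientation is ambiguous; both
  orientations are scored and the larger value kept.
- **Unique connecting interfaces.** Within an assembly, interfaces are
  single-linkage clustered at Q ≥ 0.75 (identity position maps). Each
  cluster's representative is its smallest interface id; clusters are
  visited in descending order of representative surface area. The sweep adds
  the representative to the connecting set, then consumes member interfaces:
  the first seeds two chains, later ones only when exactly one endpoint is
  already connected; it stops once every chain is covered. The member sweep
  repeats to a fixed point before moving on, so that member ordering cannot
  strand a chain — with a connected assembly the loop always terminates with
  full coverage. Assemblies whose chain/interface graph is disconnected are
  excluded from clustering (and logged by the pipeline).
- **Binary similarity and clustering.** Assemblies are only compared within
  one (assembly architecture, stoichiometry, symmetry) cell. S₁₂ = 1 iff
  every connecting interface of assembly 1 matches some unique interface of
  assembly 2 at Q ≥ q_match (checked from largest to smallest);
  S = S₁₂·S₂₁. Clusters are single-linkage components over S = 1, sorted by
  (#CFs, #entries) descending.
- **Evidence statistics.** Per UniProt, R_CF_UNPclus = CFs of that protein
  in the cluster / CFs of that protein in the whole corpus for the same
  architecture; the cluster-level ratio uses the two sums over member
  UniProts. Text output rounds to two decimals; JSON keeps full precision.
  Entries without entity keys count toward #CFs but not toward the ratio.
  When an annotation table is supplied, per-source agreement counts the
  member entries whose labelled assembly matches the cluster assembly under
  the same binary similarity; with no table the counts are absent, not zero.

## Symmetry detection

Point groups are assigned by an internal detector. Chains are grouped into
interchangeable sets — by entity (`strict_entity`) or by chain Pfam
architecture (`pseudo_by_arch`) — and every chain is superposed onto its
group's reference chain (longest; ties by chain id) by least-squares
rotation over aligned positions. Rotations with RMSD ≤ 3 Å are analysed:
a Cn label requires the n rotation angles to form a closed cycle
(k·360°/n within 8°) about a common axis (colinear within 10°); Dn
additionally requires n two-fold axes perpendicular (within 10°) to the
principal axis; 12/24/60-chain assemblies whose rotation count matches a
polyhedral group order without fitting Cn/Dn are labelled `polyhedral`.
No candidate rotations → C1; rotations without closure (e.g. open
filaments; helical symmetry is not modelled) → `unknown`. Chain-count
divisibility (n | N for Cn, 2n | N for Dn under the grouping) is enforced.
The same-architecture pseudo label is used as the comparison gate in
same-architecture cells (so an A3B3 hexamer, C3 on strict entities, joins
the D3 cell of its homo-hexamer relatives); strict labels are retained in
the report.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| Cβ pair cutoff | 12 Å | representative-point contact distance |
| atomic cutoff | 5 Å | heavy-atom contact distance |
| q_within | 0.75 | within-assembly interface clustering threshold |
| q_match | 0.5 | cross-entry interface match threshold |
| σ | 3 Å | distance-weight kernel width |
| cf_cell_tol | 0.05 | relative cell-parameter tolerance per CF |
| entity_identity | 0.95 | sequence identity for entity single linkage |
| rmsd_tol / angle_tol / axis_tol | 3 Å / 8° / 10° | symmetry detector tolerances |

The interface cutoffs and q_within are part of the method definition;
q_match is a package choice: a cross-homolog interface can be a confident
match near Q ≈ 0.7, below the within-entry 0.75 cutoff, so the cross-entry
threshold must be lower. All are exposed in `RunConfig`.

Sequence identity is defined as (identical aligned positions) / (length of
the longer sequence).

## Synthetic data

The fixture generator builds exact oligomers from a compact helical rod
(30 residues by default, 1.5 Å rise, 100° turn, all heavy atoms within
~2.6 Å of the chain axis, ±0.1 Å deterministic jitter). Rings place n
copies at 360°/n steps with 9 Å neighbour spacing, chosen so intended
neighbours meet the interface criterion while more distant chains fail the
atomic-contact clause; generation-time assertions verify the intended
contact graph and raise otherwise. Dihedral assemblies stack two rings
related by an exact perpendicular two-fold (4 Å gap); a side-by-side D2
variant connects the same C2 dimer through a different face, giving the
"two incompatible tetramers sharing one dimer" scenario. Hetero variants
reuse identical coordinates with mutated sequences (never touching
glycine), so pseudo-symmetry is exact. The toy corpus (7 entries, 6
crystal forms, one EM entry, one disconnected candidate) carries identity
HMM maps and entity labels and ships with its expected cluster manifest.

Because fixture geometry is exact, passing tests demonstrate correctness of
the algorithms, not robustness to real-data noise: conformational
variability, partial disorder, register shifts in the HMM maps, and
near-threshold interfaces are not represented. Problem sizes (30-residue
chains, ≤16 chains per assembly, 7-entry corpora, 100 randomized
crystal-form corpora) were chosen so the whole suite and the acceptance
script complete in seconds while still exercising every code path.

## Numerical choices and degenerate inputs

- Contact search uses a k-d tree; tests compare it against the O(n²)
  double loop.
- Interfaces that satisfy only the 5-atomic-contact clause have no Cβ pair
  set; their atomic pairs (at the nominal 5 Å distance) stand in for Q
  scoring so that such interfaces are still comparable.
- Surface-area sorting uses the Cβ-pair count as area proxy (only the
  descending order matters); ties break toward smaller interface id.
  Representative selection, cluster ordering, cf_id assignment and cluster
  ids are all deterministic, so identical inputs give byte-identical
  reports.
- Chains with fewer than 3 resolved residues are dropped on reading (they
  cannot support superposition); multi-model (NMR) files contribute model 1
  only.
- Monomers carry no interface evidence and are skipped by the pipeline;
  merge-deduplication keeps lattice-derived candidates over deposited ones.

## Known limitations

- Helical/filamentous and improper (S2n) symmetries are not detected.
- The detector inspects chain-onto-chain rotations only; it does not verify
  that each rotation permutes the entire assembly, which exact fixtures do
  not require but noisy near-symmetric structures might.
- Solvent-accessible surface area is not computed; the Cβ-pair count is a
  proxy adequate for ordering interfaces by size.
- Cross-entry comparison requires a shared architecture; chains without any
  domain assignment are grouped under a single "(NA)" architecture, which
  can over-merge unrelated unannotated chains.
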