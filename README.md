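# consite

Spatial clustering of evolutionarily conserved residues in protein–protein
interfaces, and binding-site prediction by ranking surface patches on the
degree of that clustering.

## The problem and who this is for

Residues that matter for a protein–protein interaction are conserved by
evolution, and they tend to sit together in space rather than being scattered
over the interface. `consite` is for structural bioinformaticians who want
to (a) quantify how clustered the conserved residues of a known interface
are, (b) partition them into spatial sub-clusters that make good targets for
scanning mutagenesis, and (c) locate a *probable* binding site on a chain of
known structure using nothing but an alignment of homologues.

## The statistics

For a set of residues with centers of mass at pairwise distances r_ij (Å),
the degree of spatial clustering is the average inverse distance

    M_s = (1 / N_pairs) Σ_{i<j} 1 / r_ij ,    N_pairs = N_s (N_s − 1) / 2 .

Close pairs dominate M_s, so a few outliers cannot mask a tight core.
Per-position conservation is the Shannon entropy s(i) = −Σ_k p_i(k) ln p_i(k)
of amino-acid *class* frequencies in the alignment column, over 7 classes
(AVLIMC / GST / DE / NQ / RK / PFYW / H) within which substitutions count as
conservative; a Kullback–Leibler variant against background class
frequencies is also available. Conserved interface residues are those with
s(i) below the interface mean ⟨s⟩_int (or ⟨s⟩_int − σ, or exactly 0), and

    ρ = M_s,cons / M_s,int

measures their clustering relative to the whole interface: ρ > 1 means the
conserved subset is clustered. Significance comes from 1000 random same-size
subsets of interface residues. Sub-clusters are cut from an average-linkage
dendrogram at 15 Å (complexes) or 21 Å (homodimers) — half the mean maximum
inter-atom distance of conserved interface residues. For prediction, every
surface residue (relative accessibility ≥ 5%) seeds a patch of surface
neighbours within a radius (fixed 15/22 Å; or half the interface's maximum
atom-pair distance; optionally constrained to one face by requiring < 110°
between per-residue solvent vectors); patches are ranked by their own ρ and
the true interface's rank is reported as a decile with a Z-score
Z = (ρ_int − ⟨ρ⟩)/σ (critical value 1.64).

## Worked example

`examples/01_interface_conservation_clustering.py` builds a toy two-chain
complex (96 residues per chain, a designed 16-residue contact per chain, 4
conserved residues planted in a tight blob) plus a depth-60 alignment, and
runs the full analysis:

```
interface residues (chain A): 16
mean interface entropy <s>_int = 0.511 nats (sd 0.295)
conserved residues (s < <s>_int): 4
M_s,cons = 0.1356 1/A   M_s,int = 0.0865 1/A
rho = 1.568  (> 1 means the conserved subset is clustered)
random-subset test: <M_s,random> = 0.0870, p = 0.0070
sub-clusters at 15 A threshold: 1
```

The conserved blob's mean inverse distance (0.136 Å⁻¹) is 1.57× that of the
whole interface, and only ~0.7% of random 4-residue subsets cluster as
tightly — the planted signal is recovered. The other examples cover patch
ranking (`02`, printing rank/decile/Z per patch method), sub-clusters and
hot-spot localization (`03`), and the file-based PDB→TSV/JSON workflow
(`04`). A thin CLI wraps the same calls:

```bash
consite simulate --seed 7 --out fixture/
consite cluster --pdb fixture/complex.pdb --msa fixture/chainA.fasta \
    --chains-a A --chains-b B --out analysis/
consite rank --pdb fixture/complex.pdb --msa fixture/chainA.fasta \
    --chain A --method 1 --radius 15 --out ranking/
```

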