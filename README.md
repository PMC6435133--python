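# matphase

Diploid haplotype assembly by low-rank matrix completion.

A diploid genome carries two haplotypes — the sequences of alleles along the
maternal and the paternal chromosome copy. Sequencing reads each observe the
alleles at a handful of nearby SNPs, and *haplotype assembly* (single-individual
phasing) reconstructs the two haplotypes from those fragmentary, error-prone
observations. Coding the wild allele as `+1` and the rare allele as `-1`, the
reads stack into an incomplete matrix **R** (reads × SNPs, zeros at unobserved
cells) that, without errors, is a masked version of a matrix of rank ≤ 2 whose
rows are the two haplotypes `h_p` and `h_m` (rank 1 when every site is
heterozygous, since then `h_m = −h_p`). Phasing becomes a matrix-completion
problem:

```
min_H  Σ_{(i,j)∈Ω} (H_ij − R_ij)²   subject to  rank(H) = 2
```

with Ω the observed-cell set. `matphase` solves it with three engines —

* **SVT** — singular value thresholding, alternating the shrinkage operator
  `D_τ(M) = U·diag(max(σ_i − τ, 0))·Vᴴ` with re-injection of the data:
  `X^k = D_τ(Y^{k−1})`, `Y^k = Y^{k−1} + δ·P_Ω(R − X^k)`;
* **nuclear-norm minimization** — the convex relaxation
  `min ‖H‖_* s.t. ‖P_Ω(H − R)‖_F ≤ ε`, solved by Douglas–Rachford splitting;
* **OPTSPACE** — trimming of over-observed rows/columns, rank-r spectral
  projection scaled by `N·l/|Ω|`, and least-squares "cleaning" by gradient
  descent on orthonormal factors —

then extracts the haplotype pair from the completed matrix (pivot rows of the
reduced row echelon form of `Hᵀ`, or the default clustered-consensus decode),
partitions real data into independently phased haplotype blocks, and evaluates
with the field's metrics: reconstruction rate
`rr = 1 − min{HD(ĥ_m,h_m), HD(ĥ_p,h_p)}/l`, switch error rate (switches per
SNP, split into short and long switch events), SNP missing rate, and block
statistics (mean span, adjusted N50).

The solvers are scikit-learn-style estimators (`SVTCompleter`,
`NuclearNormCompleter`, `OptSpaceCompleter`, and the end-to-end
`MatrixPhaser`), so they compose with sklearn tooling; thin functions
(`complete_svt`, `assemble`, …) wrap them.

## Worked example

The package ships the classic ten-SNP β2AR example: ten error-free reads over
ten bi-allelic sites with known haplotypes.

```
$ python -c "
from matphase import datasets
from matphase.io import write_fragments
write_fragments(datasets.load_b2ar_fragments(), open('fragments.txt','w'))
datasets.B2AR_SITE_MAP.write(open('sites.tsv','w'))"
$ matphase assemble --fragments fragments.txt --sites sites.tsv --solver opt -o phased.txt
phased 1 block(s) over 10 sites; 0 site(s) unphasable
$ head -4 phased.txt
BLOCK: offset: 1 len: 10 phased: 10
1       1       0       b2ar    101
2       0       0       b2ar    201
3       0       1       b2ar    301
```

All ten reads overlap into one block, every site is phased, and the per-site
codes (`0` = wild allele, `1` = rare allele, one column per haplotype) decode
to the two known haplotypes:

```
hp: ACGGCCCGGG
hm: GCACTTTACG
```

(the maternal/paternal labels are inherently arbitrary — no assembler can
tell which is which). `--solver svt` and `--solver nuc` give the same phased
block. The library route is one call:

```python
from matphase import MatrixPhaser, datasets
phaser = MatrixPhaser(solver="opt").fit(datasets.load_b2ar_read_matrix())
phaser.haplotypes_          # HaplotypePair over {+1, -1, 0=missing}
phaser.blocks_              # haplotype blocks with sub-matrices
phaser.diagnostics_         # per-block solver diagnostics
```

A simulated benchmark in the style of the standard coverage/error grids is
built in (`matphase simulate`, `matphase benchmark`, `matphase evaluate`, or
`matphase.simulate.run_benchmark`); it generates connected all-heterozygous
instances of length 700 with ~7.4 SNPs per paired-end read and uniform
contamination of the observed entries, and reports mean reconstruction rate
and switch error rate per (coverage, error, solver) cell.

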