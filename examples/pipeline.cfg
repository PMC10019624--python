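# editscan pipeline configuration (flat key = value; '#' starts a comment)

seed = 7
outdir = editscan_run

# --- simulation (omit this block and set genome_path/rna_sam/dna_sam
#     to analyse existing alignments instead)
contig_lengths = 50000
gc_content = 0.4
n_sites = 200
level_distribution = uniform:0.2,0.9   # also: fixed:0.5 | two_point:0.1,0.8,0.5,0.5
motif_bias = 0.5
hairpin_fraction = 0.1
coverage = 50
read_length = 100
error_rate = 0.001
dna_coverage = 50

# --- detection
min_depth = 5
min_level = 0.0
min_alt_reads = 2
base_quality_min = 20
fdr_level = 0.05

# --- structure
flank = 400
temperatures_c = 25,30,34
max_window = 121        # cap folded window for desk-scale runs; remove for full 801 nt
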