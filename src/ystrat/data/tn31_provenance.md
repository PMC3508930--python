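# Provenance of the packaged Tamil Nadu haplogroup frequency table

`tn31_haplogroup_freq.csv` is a curated transcription of a published table of
Y-chromosome haplogroup frequencies (%) for 31 endogamous populations
(N = 1680 men, 21 haplogroups). The machine-extracted source table displaced
one haplogroup column: in every population row and every group-total row the
value printed *after* the "Nei Gene Diversity (SD)" column is the J2-M172
frequency (header position 10 of 21); the grand-total row is not displaced.

The resolution was fixed by three checksums, all of which pass with no
residual ambiguity:

1. every population row sums to 100 +/- 0.05 %;
2. integer counts reconstructed per row (nearest integer of freq x N / 100,
   ties to even) sum exactly to the printed N for all 31 rows, and the seven
   group-total rows reconstruct *exactly* (zero count residual) as the
   column-wise sums of their member rows;
3. grand-total pooled frequencies reproduce the printed total row to
   <= 0.005 percentage points in every column (e.g. pooled J2-M172 = 9.35 %,
   pooled C-M130 count = 74).

`tn31_groupings.csv` records, per population: the seven-way major population
group (MPG) label, the tribe/caste dichotomy, the rank stratum
(TR/LOW/MID/HIGH) and the sampled district, transcribed from the published
population-description table.

The `nei_d` / `nei_sd` columns are the published per-population gene
diversity values, retained for cross-checking only; all analyses in this
package recompute diversity from the reconstructed counts.
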