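name,value,source
known_peptides,43495,results_text
putative_novel_peptides,4168,results_text
pnp_spectra_searched,14164,results_text
regex_matched_peptides,403,results_text
blastp_standard_matched,542,results_text
blastp_short_matched,674,results_text
filtered_peptides_total,904,results_text
single_spectrum_removed,1762,results_text
final_novel_peptides,1584,results_text
multi_mapping_fnps,68,results_text
clusters_total,686,results_text
cp_confident_nt_pct,86.42,results_text
known_junction_occurrences,1047488,results_text
known_junction_sites,56432,results_text
novel_junction_occurrences,1893300,results_text
novel_junction_sites,298891,results_text
known_transcripts,103707,results_text
novel_transcripts,106653,results_text
novel_events_total,1997007,results_text
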