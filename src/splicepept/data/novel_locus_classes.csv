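row,intergenic,intragenic,source
final_novel_peptides,963,585,locus_classification_table
unique_mapping_fnps,944,570,locus_classification_table
nt_clusters,69,461,locus_classification_table
nj_clusters,28,87,locus_classification_table
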