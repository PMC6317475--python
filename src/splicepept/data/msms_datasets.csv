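dataset,spectra,identified_spectra,identification_rate_pct,identified_peptides,putative_novel_peptides,source
PXD000265,253743,83083,32.74,21563,1500,msms_summary_table
PXD000313,976822,72516,7.42,17802,1182,msms_summary_table
PXD000923,87502,16584,18.95,6344,705,msms_summary_table
PXD001030,301027,29902,9.93,7678,466,msms_summary_table
PXD001058,92162,24634,26.73,9458,605,msms_summary_table
PXD002291,94400,16471,17.45,2654,172,msms_summary_table
PXD002739,34344,9151,26.65,2913,173,msms_summary_table
PXD002740,25862,10683,41.31,2934,196,msms_summary_table
PXD003156,185556,158889,85.63,8213,314,msms_summary_table
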