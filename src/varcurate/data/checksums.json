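{
  "gene_panel.tsv": "847726bb226c65bd946ce96d408816631969dcd2f9449957ef88ddfae368db4d",
  "cohort_table.tsv": "9c9216c212e84ca922cac46399f447864e28be772e32c3d828961babf27dbea7"
}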