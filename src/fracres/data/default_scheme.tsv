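low_code	go_id	label	high_code
Z11	GO:0008610	lipid biosynthetic process	Z1
Z12	GO:0008202	steroid metabolic process	Z1
Z13	GO:0006139	nucleobase containing compound metabolic process	Z1
Z14	GO:0005975	carbohydrate metabolic process	Z1
Z15	GO:0019538	protein metabolic process	Z1
Z16	GO:0019748	secondary metabolic process	Z1
Z21	GO:0016740	transferase activity	Z2
Z22	GO:0016491	oxidoreductase activity	Z2
Z23	GO:0016787	hydrolase activity	Z2
Z24	GO:0016874	ligase activity	Z2
Z25	GO:0016829	lyase activity	Z2
Z26	GO:0016853	isomerase activity	Z2
Z31	GO:0019222	regulation of metabolic process	Z3
Z32	GO:0001071	nucleic acid binding transcription factor activity	Z3
Z33	GO:0007165	signal transduction	Z3
Z34	GO:0009725	response to hormone	Z3
Z35	GO:0009266	response to temperature stimulus	Z3
Z36	GO:0006950	response to stress	Z3
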