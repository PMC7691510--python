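hgvs_c	hgvs_p	label	edit_spec
c.358-304C>G	p.Val120Glnfs*8	c.358-304C>G	{"insert_position": 357, "inserted_sequence": "CAGGCTGACCTGCATGACAGATAAGGCTTCATCAATGGCCACT"}
c.380T>A	p.Leu127*	c.380T>A	
c.409A>T	p.Lys137*	c.409A>T	
c.424G>T	p.Gly142*	c.424G>T	
c.441T>A	p.Cys147*	c.441T>A	
c.88_89insA	p.Val30Aspfs*8	c.88_89insA	
c.275_276delAA	p.Lys92Argfs*9	c.275_276delAA	
c.320dupT	p.Ser108Leufs*15	c.320dupT	
c.335dupG	p.Cys112Trpfs*11	c.335dupG	
c.355delGinsAAAAC	p.Val119Lysfs*5	c.355delGinsAAAAC	
c.379_380delTT	p.Leu127Glyfs*6	c.379_380delTT	
c.380_383dupTGGG	p.Lys129Glyfs*6	c.380_383dupTGGG	
c.401_402insTT	p.Glu134Aspfs*2	c.401_402insTT	
c.383_392dupGCAAAGGTGG	p.Asn132Glnfs*5	c.383_392dupGCAAAGGTGG	
c.435delGinsCGTTTA	p.Leu145Phefs*3	c.435delGinsCGTTTA	
c.376delG	p.Asp126Thrfs*24	c.376delG	
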