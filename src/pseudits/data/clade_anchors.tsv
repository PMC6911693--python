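label	anchor_taxa
clade I	Banqiao6,Jimengsang
clade II	Gui23,Yun7muben,M. nigra
clade 3	Yun6muben-β1
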