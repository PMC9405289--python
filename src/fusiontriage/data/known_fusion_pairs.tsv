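gene5	gene3	source
BCR	ABL1	public_fusion_catalogs
CCDC6	RET	public_fusion_catalogs
SLC34A2	ROS1	public_fusion_catalogs
FBXL20	ERBB2	public_fusion_catalogs
NCOA4	RET	public_fusion_catalogs
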