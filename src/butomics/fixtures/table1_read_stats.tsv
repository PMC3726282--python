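sample_id	raw_reads	qualified_reads	mapped_reads
C242	15535317	5552572	3177168
C483	9013667	2331738	1784966
C722	8986367	3026360	2455571
B241	9175893	2947480	1755209
B483	13434402	4733896	3005487
B724	23330644	8945794	5430235
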