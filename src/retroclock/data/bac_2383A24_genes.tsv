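# genes of BAC clone 2383A24; intronless CDS spans, 1-based inclusive
# name	start	end	strand
2383A24.1	9737	11026	+
2383A24.2	14749	16257	+
2383A24.3	19745	21019	+
2383A24.4	26839	27333	+
2383A24.5	33063	33407	+
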