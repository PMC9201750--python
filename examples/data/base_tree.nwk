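((((sp09:0.8577452283,sp07:0.8577452283):2.288251977,(((sp22:0.5874198611,(sp14:0.1956942384,sp02:0.1956942384):0.3917256227):1.454868642,(sp03:0.009265113988,sp19:0.009265113988):2.033023389):0.7317594545,((sp20:0.6461314225,(sp12:0.3831385973,sp08:0.3831385973):0.2629928251):1.918773003,(sp18:0.161532257,sp11:0.161532257):2.403372168):0.2091435325):0.3719492472):0.9065867035,((sp04:1.026879383,sp26:1.026879383):1.277099466,(sp15:2.057142444,(sp01:0.7363486543,sp05:0.7363486543):1.32079379):0.2468364051):1.74860506):0.9474160914,(((sp13:1.87668953,sp24:1.87668953):1.86388208,(sp16:1.494453092,(sp10:1.419585266,sp25:1.419585266):0.07486782573):2.246118517):0.9677702145,(sp17:4.246517691,(sp21:2.440760338,(sp23:0.9985361014,sp06:0.9985361014):1.442224237):1.805757353):0.4618241327):0.2916581761);
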