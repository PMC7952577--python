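>PP7 wild-type PCP binding hairpin (25 nt), canonical literature sequence
UAAGGAGUUUAUAUGGAAACCCUUA
>MS2 wild-type MCP binding hairpin (19 nt), canonical literature sequence
ACAUGAGGAUUACCCAUGU
>Qbeta wild-type QCP binding hairpin (20 nt), canonical literature sequence
AUGCAUGUCUAAGACAGCAU
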