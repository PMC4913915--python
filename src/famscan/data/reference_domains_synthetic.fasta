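>synref_I|I synthetic template domain
WRKYGQKLNDMSVIKKVCMIVVCEILNFVFQYGRSFIAPYILKQPHAH
>synref_IIa|IIa synthetic template domain
WRKYGQKQMGMGAINIVCRFQKCAPFALTINLPYIPNRIARTKQVHSH
>synref_IIb|IIb synthetic template domain
WRKYGQKINLRTRFAVYCKFPFCKTNTKDTDKSNMDVQARENKMTHIH
>synref_IIc|IIc synthetic template domain
WRKYGQKGSAYDVEISICMNANCLRLALQYDPEVSVRISELNVFVHQH
>synref_IId|IId synthetic template domain
WRKYGQKDQMVMFTPAECLVYNCYEAYVSEAQKVSDQYATAFFQQHFH
>synref_IIe|IIe synthetic template domain
WRKYGQKYFREMESTTGCIRPRCSDYDAFPIIPEFANAAVPEGFMHNH
>synref_III|III synthetic template domain
WRKYGQKYITIFDAPYNCKKFELEVCYMEKDRAATGFDNLQRPFEFSDGHIC
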