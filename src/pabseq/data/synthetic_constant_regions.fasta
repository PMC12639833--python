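>LC_CONST synthetic light-chain constant-region stand-in (107 aa)
RTVAAPSVDEKSTEAIPSLTPTLKYIGLKMADRVKGDLTWLIELPPSCEGAYIPAHKVGRTTDNCGVAKYTKQGKPGSVGFTQASPEEGLRVVVKNESTWVFNRGEC
>FD_CONST synthetic CH1+hinge constant-region stand-in ending at the IdeS site (105 aa)
ASTKTPSVSESSCVFKLIPRVLMYVDQKIRTQKPGMGEYHNVGMDIGAGTAFDYNYTEESEKPQKGKYSDLDLFCSMEECKIKTYNGDIFILDKSYSCPAPELLG
>FC_HALF synthetic Fc/2 stand-in (210 aa)
GPSVFLFPAVLALLVSTLDPNHHQDNQCKDSAPVCAVATNKASCSIERPRFYDSANSVNVPDKPGEAVFKEYFATNSTTNQKSKSQYVAELMYAYVYSKFNIASCHLNITRLNDTLPLCVDAVNIGIMKDIGVVKLYKPYKHKSTRLKTAPAVGELSQEVEYYPPVKVDLTFTIDLFFLNVPFADHRHYKHVDKTAFAVHHASLSLSPGK
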